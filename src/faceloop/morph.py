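"""Mapping from the normalized feedback signal to the face display.

The display is a face morphed along a neutral-to-emotional continuum in 30
steps: index 0 is the lowest valence (neutral, 0%) and index 30 the highest
(full happy or fearful expression, 100%). Group polarity decides whether a
stronger feedback signal pushes the display toward the emotional extreme
(positive loop, task-congruent groups) or away from it (negative loop).

Faces are represented as abstract parameter vectors (landmark-like
coordinates); blending is affine between the neutral and emotional vectors,
which keeps the geometry of the morph testable without any image I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_MORPH_STEPS = 30  # indices 0..30 inclusive -> 31 display states


@dataclass(frozen=True)
class FaceParamVector:
    """Abstract stand-in for one model's photographs."""

    id: str
    gender: str  # "m" or "f"
    neutral_params: np.ndarray
    emotional_params: np.ndarray

    def __post_init__(self) -> None:
        if len(self.neutral_params) != len(self.emotional_params):
            raise ValueError("neutral and emotional parameter vectors differ in length")


@dataclass(frozen=True)
class MorphFrame:
    face_id: str
    emotion: str  # "happy" or "fear"
    morph_index: int

    @property
    def valence_fraction(self) -> float:
        return self.morph_index / N_MORPH_STEPS


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def signal_to_morph_index(normalized: float, polarity: int) -> int:
    """Discretize the normalized signal onto the 0..30 morph continuum.

    polarity +1 (positive loop): higher signal -> more intense expression.
    polarity -1 (negative loop): the mapping is mirrored. Rounding is
    half-away-from-zero so the midpoint lands on index 15 on any platform.
    """
    if not 0.0 <= normalized <= 1.0:
        raise ValueError(f"normalized value {normalized} outside [0, 1]")
    if polarity not in (+1, -1):
        raise ValueError(f"polarity must be +1 or -1, got {polarity}")
    s = normalized if polarity == +1 else 1.0 - normalized
    return _round_half_away(N_MORPH_STEPS * s)


def blend_face(face: FaceParamVector, morph_index: int) -> np.ndarray:
    """Affine blend (1-w)*neutral + w*emotional with w = morph_index/30."""
    if not 0 <= morph_index <= N_MORPH_STEPS:
        raise ValueError(f"morph index {morph_index} outside [0, {N_MORPH_STEPS}]")
    w = morph_index / N_MORPH_STEPS
    return (1.0 - w) * np.asarray(face.neutral_params) + w * np.asarray(
        face.emotional_params
    )


def make_stimulus_set(
    n_faces: int = 30, n_female: int = 15, n_params: int = 8, seed: int = 0
) -> list[FaceParamVector]:
    """Synthetic stimulus set standing in for a face-photograph database.

    Parameter vectors are random landmark-like coordinates; the emotional
    vector is the neutral one plus a smooth displacement.
    """
    rng = np.random.default_rng(seed)
    faces = []
    for i in range(n_faces):
        gender = "f" if i < n_female else "m"
        neutral = rng.normal(0.0, 1.0, n_params)
        emotional = neutral + rng.normal(0.5, 0.3, n_params)
        faces.append(
            FaceParamVector(
                id=f"face{i:03d}", gender=gender,
                neutral_params=neutral, emotional_params=emotional,
            )
        )
    return faces


def assign_faces(
    stimulus_set: list[FaceParamVector],
    seed: int,
    n_blocks: int = 4,
    n_runs: int = 4,
) -> list[list[str]]:
    """Assign one novel face per regulation block, gender-counterbalanced.

    Returns per-run lists of face ids: n_runs * n_blocks distinct ids with
    equal male/female counts, drawn without replacement.
    """
    total = n_blocks * n_runs
    males = [f.id for f in stimulus_set if f.gender == "m"]
    females = [f.id for f in stimulus_set if f.gender == "f"]
    if len(males) < total // 2 or len(females) < total // 2 or total % 2:
        raise ValueError(
            f"stimulus set with {len(males)} male / {len(females)} female faces "
            f"cannot supply {total} unique gender-balanced faces"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(males, total // 2, replace=False)) + list(
        rng.choice(females, total // 2, replace=False)
    )
    chosen = list(rng.permutation(chosen))
    return [chosen[r * n_blocks : (r + 1) * n_blocks] for r in range(n_runs)]


def stimulus_set_to_frame(faces: list[FaceParamVector]) -> pd.DataFrame:
    """Tabular view of a stimulus set (id, gender, parameter columns)."""
    rows = []
    for f in faces:
        row = {"id": f.id, "gender": f.gender}
        row.update({f"neutral_{j}": v for j, v in enumerate(f.neutral_params)})
        row.update({f"emotional_{j}": v for j, v in enumerate(f.emotional_params)})
        rows.append(row)
    return pd.DataFrame(rows)
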