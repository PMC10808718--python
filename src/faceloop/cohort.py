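"""Generative simulator of closed-loop face-feedback participants.

One simulated participant is a 4-region neural system (region order
V1, FFA, Amy, mOFC) obeying the bilinear state equation

    dz/dt = (A + u_face * B_face + u_int * B_int) z + C [u_face, u_int]'

driven by two inputs: u_face, a boxcar that is 1 while a face is displayed
(regulation blocks), and u_int, the displayed emotional intensity
(morph index / 30). Neural states are observed through convolution with the
canonical HRF, sampled once per TR with additive Gaussian noise. The
measured amygdala value is fed through the causal online chain
(:mod:`faceloop.online`) and mapped to the next morph index with the
group's loop polarity (:mod:`faceloop.morph`), closing the loop with a
one-volume lag.

The block design is the trained paradigm: four 40-s regulation blocks
interleaved with four 20-s baseline blocks (mental counting, no face),
preceded by dummy volumes that are discarded from all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import CanonicalHrf, build_chrf
from .morph import N_MORPH_STEPS, signal_to_morph_index
from .online import ChainSettings, OnlineChain

REGIONS = ("V1", "FFA", "Amy", "mOFC")
N_REGIONS = 4
AMY = REGIONS.index("Amy")

# directed edges that may carry coupling (besides the always-present
# self-connections); shared with the DCM model space
CANDIDATE_EDGES = (
    ("V1", "FFA"),
    ("V1", "Amy"),
    ("V1", "mOFC"),
    ("FFA", "Amy"),
    ("Amy", "FFA"),
    ("mOFC", "Amy"),
    ("Amy", "mOFC"),
)


class UnstableParametersError(RuntimeError):
    """Raised when a latent trajectory exceeds the divergence bound."""


# --------------------------------------------------------------------- config


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants of one neurofeedback session."""

    tr: float = 1.0
    n_dummy: int = 5
    baseline_len: float = 20.0
    regulation_len: float = 40.0
    n_blocks_per_kind: int = 4
    n_runs: int = 4
    n_per_group: int = 16
    integration_dt: float = 0.1
    obs_noise_sd: float = 0.2
    neural_noise_sd: float = 0.05
    pad_pre: float = 0.0
    pad_post: float = 0.0
    divergence_bound: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.integration_dt <= 0:
            raise ValueError("tr and integration_dt must be positive")
        if self.baseline_len <= 0 or self.regulation_len <= 0:
            raise ValueError("block durations must be positive")
        steps = self.tr / self.integration_dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("integration_dt must divide tr")
        for name in ("n_dummy", "n_blocks_per_kind", "n_runs", "n_per_group"):
            if getattr(self, name) < 1 and name != "n_dummy":
                raise ValueError(f"{name} must be >= 1")
        if self.obs_noise_sd < 0 or self.neural_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def steps_per_tr(self) -> int:
        return round(self.tr / self.integration_dt)


@dataclass(frozen=True)
class GroupSpec:
    """Emotion condition x regulation direction -> loop polarity.

    Task-congruent groups (happy-up, fear-down) run a positive closed loop:
    more amygdala activity means a more intense expression. The incongruent
    groups (happy-down, fear-up) run the mirrored negative loop.
    """

    condition: str  # "happy" | "fear"
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.condition not in ("happy", "fear"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def name(self) -> str:
        return f"{self.condition}-{self.direction}"

    @property
    def congruent(self) -> bool:
        return (self.condition == "happy") == (self.direction == "up")

    @property
    def polarity(self) -> int:
        return +1 if self.congruent else -1


ALL_GROUPS = (
    GroupSpec("happy", "up"),
    GroupSpec("happy", "down"),
    GroupSpec("fear", "down"),
    GroupSpec("fear", "up"),
)


# ------------------------------------------------------------- neural params


def _edge_mask(edges=CANDIDATE_EDGES) -> np.ndarray:
    mask = np.eye(N_REGIONS, dtype=bool)
    for src, dst in edges:
        mask[REGIONS.index(dst), REGIONS.index(src)] = True
    return mask


@dataclass(frozen=True)
class NeuralParams:
    """Bilinear coupling parameters (Hz), region order V1, FFA, Amy, mOFC.

    A[i, j] couples region j -> region i. B_face and B_int modulate the
    coupling while a face is displayed / in proportion to its intensity.
    C holds the driving-input weights (columns: face, intensity), entering
    at V1 only.
    """

    A: np.ndarray
    B_face: np.ndarray
    B_int: np.ndarray
    C: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        if not self.validate:
            # estimation code may construct candidates outside the generative
            # constraints (e.g. a transiently non-negative self-connection)
            return
        A = np.asarray(self.A, float)
        if A.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("A must be 4x4")
        if np.any(np.diag(A) >= 0):
            raise ValueError("all A self-connections must be strictly negative")
        allowed = _edge_mask()
        for name, M in (("A", A), ("B_face", self.B_face), ("B_int", self.B_int)):
            M = np.asarray(M, float)
            if M.shape != (N_REGIONS, N_REGIONS):
                raise ValueError(f"{name} must be 4x4")
            if np.any(M[~allowed] != 0.0):
                raise ValueError(f"{name} has coupling outside the allowed edge set")
        C = np.asarray(self.C, float)
        if C.shape != (N_REGIONS, 2):
            raise ValueError("C must be 4x2 (face, intensity)")
        if np.any(C[1:, :] != 0.0):
            raise ValueError("driving input may enter V1 only")


def default_neural_params(
    b_ffa_amy: float = 0.2,
    b_mofc_amy: float = -0.2,
    self_decays: tuple = (-0.6, -0.7, -0.5, -0.25),
) -> NeuralParams:
    """Template ground-truth parameters for a simulated participant.

    Face input drives V1; the ventral stream (V1 -> FFA -> Amy) carries the
    stimulus; mOFC exerts (by default inhibitory) modulated influence on the
    amygdala. All magnitudes are in the sub-Hz range typical of bilinear
    effective-connectivity estimates. Self-decay rates differ per region
    (sensory regions fast, prefrontal cortex slow), giving each region a
    distinct time constant — without this heterogeneity the FFA and mOFC
    time courses are nearly proportional and their influences on the
    amygdala cannot be told apart by any estimator.
    """
    A = np.diag(np.asarray(self_decays, float))
    edges_a = {
        ("V1", "FFA"): 0.4,
        ("V1", "Amy"): 0.15,
        ("V1", "mOFC"): 0.15,
        ("FFA", "Amy"): 0.2,
        ("Amy", "FFA"): 0.05,
        ("mOFC", "Amy"): -0.1,
        ("Amy", "mOFC"): 0.2,
    }
    for (src, dst), w in edges_a.items():
        A[REGIONS.index(dst), REGIONS.index(src)] = w
    B_face = np.zeros((N_REGIONS, N_REGIONS))
    B_face[REGIONS.index("Amy"), REGIONS.index("FFA")] = b_ffa_amy
    B_face[REGIONS.index("Amy"), REGIONS.index("mOFC")] = b_mofc_amy
    B_int = np.zeros((N_REGIONS, N_REGIONS))
    B_int[REGIONS.index("Amy"), REGIONS.index("FFA")] = 0.15
    C = np.zeros((N_REGIONS, 2))
    C[0, 0] = 0.4   # face boxcar -> V1
    C[0, 1] = 0.15  # displayed intensity -> V1
    return NeuralParams(A=A, B_face=B_face, B_int=B_int, C=C)


# --------------------------------------------------------------- block design


@dataclass(frozen=True)
class BlockDesign:
    """Ordered baseline/regulation blocks plus volume bookkeeping.

    Onsets are seconds from the first retained (post-dummy) volume.
    """

    blocks: tuple  # of (onset, duration, kind)
    n_volumes: int
    dummy_volumes: int
    tr: float

    @property
    def n_retained(self) -> int:
        return self.n_volumes - self.dummy_volumes

    def regulation_blocks(self) -> list[tuple[float, float]]:
        return [(o, d) for o, d, k in self.blocks if k == "regulation"]

    def boxcar(self, step: float | None = None) -> np.ndarray:
        """Regulation indicator sampled at ``step`` (default TR) over the
        retained period."""
        step = self.tr if step is None else step
        n = round(self.n_retained * self.tr / step)
        t = np.arange(n) * step
        u = np.zeros(n)
        for onset, dur in self.regulation_blocks():
            u[(t >= onset) & (t < onset + dur)] = 1.0
        return u

    def block_of_volume(self, volume: int) -> tuple[str, int]:
        """(kind, block ordinal within kind, 1-based) for a retained volume."""
        t = volume * self.tr
        counts = {"baseline": 0, "regulation": 0}
        for onset, dur, kind in self.blocks:
            counts[kind] += 1
            if onset <= t < onset + dur:
                return kind, counts[kind]
        return "rest", 0


def make_block_design(config: SimulationConfig) -> BlockDesign:
    """Alternating baseline/regulation blocks starting with baseline."""
    blocks = []
    t = config.pad_pre
    for _ in range(config.n_blocks_per_kind):
        blocks.append((t, config.baseline_len, "baseline"))
        t += config.baseline_len
        blocks.append((t, config.regulation_len, "regulation"))
        t += config.regulation_len
    total = t + config.pad_post
    n_task = total / config.tr
    if abs(n_task - round(n_task)) > 1e-9:
        raise ValueError("total task duration must be a whole number of volumes")
    return BlockDesign(
        blocks=tuple(blocks),
        n_volumes=round(n_task) + config.n_dummy,
        dummy_volumes=config.n_dummy,
        tr=config.tr,
    )


# ---------------------------------------------------------------- integration


def integrate_neural(
    params: NeuralParams,
    face_input: np.ndarray,
    intensity_input: np.ndarray,
    dt: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    z0: np.ndarray | None = None,
    extra_input: np.ndarray | None = None,
    divergence_bound: float = 1e3,
) -> np.ndarray:
    """Euler-Maruyama integration of the bilinear state equation.

    ``face_input`` and ``intensity_input`` are sampled on the dt grid;
    ``extra_input``, if given, is an additive per-region drive (n x 4) used
    to model endogenous regulation effort. Returns the (n x 4) trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    uf = np.asarray(face_input, float)
    ui = np.asarray(intensity_input, float)
    if uf.shape != ui.shape:
        raise ValueError("face and intensity inputs must share the dt grid")
    n = uf.size
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd * np.sqrt(dt), (n, N_REGIONS))
        if noise_sd > 0
        else None
    )
    z = np.zeros(N_REGIONS) if z0 is None else np.asarray(z0, float).copy()
    out = np.empty((n, N_REGIONS))
    A, Bf, Bi, C = params.A, params.B_face, params.B_int, params.C
    for k in range(n):
        J = A + uf[k] * Bf + ui[k] * Bi
        drive = C @ (uf[k], ui[k])
        if extra_input is not None:
            drive = drive + extra_input[k]
        # Heun (RK2) drift step; noise added afterwards (additive diffusion)
        f0 = J @ z + drive
        f1 = J @ (z + dt * f0) + drive
        z = z + 0.5 * dt * (f0 + f1)
        if noise is not None:
            z = z + noise[k]
        if np.any(np.abs(z) > divergence_bound):
            raise UnstableParametersError(
                f"latent state exceeded {divergence_bound} at step {k}"
            )
        out[k] = z
    return out


def hemodynamic_observe(
    neural: np.ndarray,
    hrf: CanonicalHrf,
    tr: float,
    obs_noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Convolve latent states with the canonical kernel and sample at TR.

    ``neural`` is (n x regions) on the dt grid; the BOLD sample for volume v
    is the convolution evaluated at the last dt sample of that volume.
    """
    neural = np.atleast_2d(np.asarray(neural, float))
    if neural.shape[0] < neural.shape[1]:
        neural = neural.T
    dt = hrf.dt if dt is None else dt
    kernel = hrf.kernel_dt
    if kernel.size > neural.shape[0]:
        raise ValueError("HRF kernel longer than the neural series")
    sub = round(tr / dt)
    idx = np.arange(sub - 1, neural.shape[0], sub)
    bold = np.empty((idx.size, neural.shape[1]))
    for r in range(neural.shape[1]):
        conv = np.convolve(neural[:, r], kernel)[: neural.shape[0]] * dt
        bold[:, r] = conv[idx]
    if obs_noise_sd > 0:
        rng = np.random.default_rng(seed)
        bold = bold + rng.normal(0.0, obs_noise_sd, bold.shape)
    return bold


def _motion_nuisance(n: int, rng: np.random.Generator) -> np.ndarray:
    """Six smooth low-amplitude random walks standing in for realignment
    parameters (3 translations mm, 3 rotations rad)."""
    steps = rng.normal(0.0, 0.02, (n, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for j in range(6):
        walk[:, j] = np.convolve(walk[:, j], kernel, mode="same")
    return walk


# ---------------------------------------------------------------- closed loop


@dataclass
class RunRecording:
    """Everything measured (and the latent truth) for one closed-loop run.

    All per-volume series cover retained volumes only (dummies discarded).
    ``neural_truth`` stays on the fine dt grid for diagnostic use.
    """

    roi_bold: np.ndarray        # (n_retained, 4)
    amy_feedback_raw: np.ndarray
    norm_feedback: np.ndarray   # online-chain normalized signal in [0, 1]
    despiked: np.ndarray        # kalman-processed amygdala series
    morph_trace: np.ndarray     # int morph index per volume
    neural_truth: np.ndarray    # (n_steps, 4) on the dt grid (retained period)
    design: BlockDesign
    motion_nuisance: np.ndarray
    group: GroupSpec
    run_index: int = 1
    face_ids: tuple = ()


def simulate_run_closed_loop(
    params: NeuralParams,
    group: GroupSpec,
    config: SimulationConfig,
    chain_settings: ChainSettings | None = None,
    seed: int | None = None,
    hrf: CanonicalHrf | None = None,
    regulation_effort: float = 0.0,
    habituation_slope: float = 0.0,
    run_index: int = 1,
    face_ids: tuple = (),
) -> RunRecording:
    """Simulate one neurofeedback run with the display in the loop.

    Per retained volume: the currently displayed morph index (lagged one
    volume, initial display neutral = index 0) sets u_int; the neural state
    integrates across one TR; the amygdala BOLD observation enters the
    online chain; its normalized output is mapped through the group's
    polarity to the next morph index. Baseline blocks show a fixation dot
    (u_face = 0, u_int = 0, morph recorded as 0).

    ``regulation_effort`` adds a constant endogenous drive to the amygdala
    during regulation blocks (positive = upregulation effort);
    ``habituation_slope`` changes that drive per successive block.
    """
    hrf = hrf or build_chrf(tr=config.tr, dt=config.integration_dt)
    design = make_block_design(config)
    rng = np.random.default_rng(seed)
    sub = config.steps_per_tr
    dt = config.integration_dt
    n_total = design.n_volumes
    n_dummy = design.dummy_volumes
    n_ret = design.n_retained
    n_steps_total = n_total * sub

    # pre-drawn noise so the amygdala loop value and the recorded ROI value
    # are the same realization
    obs_noise = (
        rng.normal(0.0, config.obs_noise_sd, (n_total, N_REGIONS))
        if config.obs_noise_sd > 0
        else np.zeros((n_total, N_REGIONS))
    )
    neural_noise = (
        rng.normal(0.0, config.neural_noise_sd * np.sqrt(dt), (n_steps_total, N_REGIONS))
        if config.neural_noise_sd > 0
        else np.zeros((n_steps_total, N_REGIONS))
    )

    chain = OnlineChain(settings=chain_settings or ChainSettings())
    kernel = hrf.kernel_dt
    A, Bf, Bi, C = params.A, params.B_face, params.B_int, params.C

    z = np.zeros(N_REGIONS)
    neural = np.zeros((n_steps_total, N_REGIONS))
    morph_index = 0  # initial neutral display before any feedback
    morph_trace = np.zeros(n_ret, dtype=int)
    raw_amy = np.zeros(n_ret)
    norm_fb = np.zeros(n_ret)
    despiked = np.zeros(n_ret)
    was_spike = np.zeros(n_ret, dtype=bool)

    for v in range(n_total):
        retained_v = v - n_dummy  # volume index relative to task origin
        if retained_v >= 0:
            kind, block_no = design.block_of_volume(retained_v)
        else:
            kind, block_no = "baseline", 0
        in_reg = kind == "regulation"
        uf = 1.0 if in_reg else 0.0
        ui = (morph_index / N_MORPH_STEPS) if in_reg else 0.0
        effort = (
            regulation_effort + habituation_slope * (block_no - 1) if in_reg else 0.0
        )
        J = A + uf * Bf + ui * Bi
        drive = C @ (uf, ui)
        drive = drive + np.array([0.0, 0.0, effort, 0.0])
        for s in range(sub):
            k = v * sub + s
            f0 = J @ z + drive
            f1 = J @ (z + dt * f0) + drive
            z = z + 0.5 * dt * (f0 + f1) + neural_noise[k]
            if np.any(np.abs(z) > config.divergence_bound):
                raise UnstableParametersError(
                    f"latent state exceeded {config.divergence_bound} "
                    f"at volume {v}"
                )
            neural[k] = z
        # BOLD observation at the end of this volume
        k_end = (v + 1) * sub - 1
        lo = max(0, k_end - kernel.size + 1)
        seg = neural[lo : k_end + 1]
        y_amy = float(seg[::-1, AMY] @ kernel[: seg.shape[0]]) * dt
        y_amy += obs_noise[v, AMY]
        if retained_v >= 0:
            raw_amy[retained_v] = y_amy
            sample = chain.process_volume(y_amy, retained_v)
            despiked[retained_v] = sample.despiked
            norm_fb[retained_v] = sample.normalized
            was_spike[retained_v] = sample.was_spike
            morph_index = signal_to_morph_index(sample.normalized, group.polarity)
            morph_trace[retained_v] = morph_index if in_reg else 0

    # full 4-region observation over the retained period (same noise draw)
    bold_all = hemodynamic_observe(neural, hrf, config.tr, 0.0, dt=dt)
    roi_bold = bold_all[n_dummy:] + obs_noise[n_dummy:]
    roi_bold[:, AMY] = raw_amy  # identical by construction; keep exact

    return RunRecording(
        roi_bold=roi_bold,
        amy_feedback_raw=raw_amy,
        norm_feedback=norm_fb,
        despiked=despiked,
        morph_trace=morph_trace,
        neural_truth=neural[n_dummy * sub :],
        design=design,
        motion_nuisance=_motion_nuisance(n_ret, rng),
        group=group,
        run_index=run_index,
        face_ids=tuple(face_ids),
    )


# -------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class EffectScenario:
    """Which groups truly regulate, per run, and the psychometric shifts.

    ``regulation_amp[group][run-1]`` is the endogenous amygdala drive during
    regulation blocks (signal units; positive = upregulation) and
    ``habituation[group][run-1]`` its per-block decrement within a run.
    ``psychometric_shift[scale]`` is added to every participant's
    post-training score.
    """

    name: str
    regulation_amp: dict
    habituation: dict
    psychometric_shift: dict = field(default_factory=dict)

    def validate(self) -> None:
        known = {g.name for g in ALL_GROUPS}
        for table in (self.regulation_amp, self.habituation):
            unknown = set(table) - known
            if unknown:
                raise ValueError(f"scenario references unknown groups: {sorted(unknown)}")


def null_scenario() -> EffectScenario:
    """No regulation anywhere: purely stimulus-driven dynamics."""
    zeros = {g.name: (0.0, 0.0, 0.0, 0.0) for g in ALL_GROUPS}
    return EffectScenario("null", dict(zeros), dict(zeros), {})


def reference_scenario() -> EffectScenario:
    """Default study conditions: fear-down downregulates in the last two
    runs with within-run habituation in runs 3-4; fear-up upregulates early
    with late habituation; happy groups show no reliable change; no
    psychometric shifts."""
    amp = {
        "happy-up": (0.15, 0.15, 0.15, 0.15),
        "happy-down": (0.0, 0.0, 0.0, 0.0),
        "fear-down": (0.1, 0.0, -0.3, -0.3),
        "fear-up": (0.25, 0.25, 0.15, 0.0),
    }
    hab = {
        "happy-up": (0.0, 0.0, 0.0, 0.0),
        "happy-down": (0.0, 0.0, 0.0, 0.0),
        "fear-down": (0.0, 0.0, -0.08, -0.12),
        "fear-up": (0.0, 0.0, 0.0, -0.1),
    }
    return EffectScenario("reference", amp, hab, {"panas_pos": 0.0, "panas_neg": 0.0, "sds": 0.0})


PSYCHOMETRIC_BASELINES = {  # (mean, sd) of healthy-adult pre scores
    "panas_pos": (30.0, 5.0),
    "panas_neg": (14.0, 4.0),
    "sds": (33.0, 6.0),
}


@dataclass
class Participant:
    id: str
    group: GroupSpec
    params: NeuralParams
    runs: list
    scores: dict  # {scale: (pre, post)}
    age: float = 25.0
    gender: str = "f"


@dataclass
class CohortDataset:
    config: SimulationConfig
    scenario: EffectScenario
    participants: list

    def by_group(self, name: str) -> list:
        return [p for p in self.participants if p.group.name == name]


def simulate_cohort(
    config: SimulationConfig | None = None,
    scenario: EffectScenario | None = None,
    chain_settings: ChainSettings | None = None,
) -> CohortDataset:
    """Simulate the full four-group cohort, deterministically from the
    master seed (per-participant seeds are spawned from it)."""
    config = config or SimulationConfig()
    scenario = scenario or reference_scenario()
    scenario.validate()
    ss = np.random.SeedSequence(config.seed)
    participants = []
    pid = 0
    for group in ALL_GROUPS:
        amps = scenario.regulation_amp.get(group.name, (0.0,) * config.n_runs)
        habs = scenario.habituation.get(group.name, (0.0,) * config.n_runs)
        for j in range(config.n_per_group):
            child = ss.spawn(1)[0]
            p_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(p_seed)
            params = default_neural_params(
                b_ffa_amy=0.2 + rng.normal(0, 0.03),
                b_mofc_amy=-0.2 + rng.normal(0, 0.03),
            )
            runs = []
            for r in range(config.n_runs):
                runs.append(
                    simulate_run_closed_loop(
                        params,
                        group,
                        config,
                        chain_settings=chain_settings,
                        seed=int(rng.integers(2**31)),
                        regulation_effort=float(amps[r]) if r < len(amps) else 0.0,
                        habituation_slope=float(habs[r]) if r < len(habs) else 0.0,
                        run_index=r + 1,
                    )
                )
            scores = {}
            for scale, (mu, sd) in PSYCHOMETRIC_BASELINES.items():
                pre = float(rng.normal(mu, sd))
                shift = float(scenario.psychometric_shift.get(scale, 0.0))
                post = pre + shift + float(rng.normal(0.0, 2.0))
                scores[scale] = (pre, post)
            participants.append(
                Participant(
                    id=f"sub-{pid + 1:03d}",
                    group=group,
                    params=params,
                    runs=runs,
                    scores=scores,
                    age=float(rng.normal(25.0, 4.5)),
                    gender="f" if j < config.n_per_group / 2 else "m",
                )
            )
            pid += 1
    return CohortDataset(config=config, scenario=scenario, participants=participants)
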