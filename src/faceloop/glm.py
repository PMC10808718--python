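"""Offline run-level GLM with the circularity-aware design matrix.

A closed-loop paradigm is inherently circular: the stimulus intensity
depends on the measured target-region activity, which in turn responds to
the stimulus. The run-level design matrix disentangles three sources:

* x1 — the regulation task in general: the regulation-block boxcar
  convolved with the canonical HRF;
* x2 — the response to the displayed emotional intensity: the normalized
  online feedback signal convolved with the canonical HRF (a parametric
  modulator of the block design);
* x3 — the residual feedback-source signal: the normalized amygdala signal
  with x1 and x2 (and an intercept) regressed out, hence orthogonal to
  both by construction.

Six realignment nuisance columns and an intercept complete the design.
x2 is deliberately *not* orthogonalized to x1; the collinearity between
them is surfaced as a diagnostic instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BlockDesign
from .hrf import CanonicalHrf, build_chrf, convolve_causal

RANK_TOL = 1e-8


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names the offending columns."""


# ----------------------------------------------------------------- regressors


def build_regressor_x1(design: BlockDesign, hrf: CanonicalHrf) -> np.ndarray:
    """Regulation boxcar convolved with the canonical kernel, at TR."""
    dt = hrf.dt
    boxcar = design.boxcar(step=dt)
    conv = convolve_causal(boxcar, hrf.kernel_dt, step=dt)
    sub = round(design.tr / dt)
    return conv[sub - 1 :: sub][: design.n_retained]


def build_regressor_x2(norm_signal: np.ndarray, hrf: CanonicalHrf) -> np.ndarray:
    """Normalized feedback series convolved with the TR-sampled kernel."""
    sig = np.asarray(norm_signal, float)
    return convolve_causal(sig, hrf.kernel_tr, step=1.0)


def build_regressor_x3(
    raw_norm_signal: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """Residual of the normalized signal on [intercept, x1, x2].

    If [intercept, x1, x2] is rank deficient (e.g. x2 collinear with x1),
    the residual is taken against the maximal independent column subset.
    """
    y = np.asarray(raw_norm_signal, float)
    if not (y.size == x1.size == x2.size):
        raise ValueError("x1, x2 and the signal must have equal length")
    X = np.column_stack([np.ones_like(y), x1, x2])
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > RANK_TOL * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class DesignMatrix:
    """Circularity-aware design: x1, x2, x3 + nuisance + intercept."""

    frame: pd.DataFrame
    collinearity_x1_x2: float  # |corr(x1, x2)| diagnostic

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_design_matrix(
    design: BlockDesign,
    norm_signal: np.ndarray,
    motion: np.ndarray | None = None,
    hrf: CanonicalHrf | None = None,
) -> DesignMatrix:
    """Assemble the full run-level design matrix from a run's outputs."""
    hrf = hrf or build_chrf(tr=design.tr)
    x1 = build_regressor_x1(design, hrf)
    x2 = build_regressor_x2(norm_signal, hrf)
    x3 = build_regressor_x3(norm_signal, x1, x2)
    cols = {"x1_task": x1, "x2_nf_response": x2, "x3_nf_signal": x3}
    if motion is not None:
        motion = np.asarray(motion, float)
        for j in range(motion.shape[1]):
            cols[f"motion_{j + 1}"] = motion[:, j]
    cols["intercept"] = np.ones(design.n_retained)
    sx1, sx2 = np.std(x1), np.std(x2)
    coll = float(np.abs(np.corrcoef(x1, x2)[0, 1])) if sx1 > 0 and sx2 > 0 else 1.0
    return DesignMatrix(frame=pd.DataFrame(cols), collinearity_x1_x2=coll)


# ------------------------------------------------------------ model / results


class RunGLM:
    """Ordinary least-squares GLM for one run's ROI series.

    Parameters
    ----------
    endog : array
        Per-volume ROI signal.
    design : DesignMatrix or DataFrame
        Full design with named columns.
    """

    def __init__(self, endog: np.ndarray, design: DesignMatrix | pd.DataFrame):
        self.endog = np.asarray(endog, float)
        self.design = design.frame if isinstance(design, DesignMatrix) else design
        if self.endog.size != len(self.design):
            raise ValueError("endog and design length mismatch")
        X = self.design.to_numpy()
        rank = np.linalg.matrix_rank(X, tol=RANK_TOL * np.abs(X).max())
        if rank < X.shape[1]:
            # identify the first column that is a linear combination of earlier ones
            bad = []
            for j in range(1, X.shape[1] + 1):
                if np.linalg.matrix_rank(X[:, :j], tol=RANK_TOL * np.abs(X).max()) < j:
                    bad.append(self.design.columns[j - 1])
            raise RankDeficientError(
                f"design matrix rank deficient; collinear columns: {bad}"
            )

    def fit(self) -> "RunGLMResults":
        X = self.design.to_numpy()
        y = self.endog
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = y.size - X.shape[1]
        sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        return RunGLMResults(
            params=pd.Series(beta, index=self.design.columns),
            bse=pd.Series(se, index=self.design.columns),
            resid=resid,
            sigma2=sigma2,
            df_resid=dof,
        )


@dataclass
class RunGLMResults:
    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    sigma2: float
    df_resid: int

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> pd.DataFrame:
        from scipy import stats

        t = self.tvalues
        p = 2 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "t": t, "p": p}
        )


def fit_run_glm(
    roi_series: np.ndarray, design: DesignMatrix | pd.DataFrame
) -> RunGLMResults:
    """Convenience wrapper: build the model and fit in one call."""
    return RunGLM(roi_series, design).fit()


# -------------------------------------------------------------- block betas


def block_regressors(design: BlockDesign, hrf: CanonicalHrf | None = None) -> np.ndarray:
    """One HRF-convolved boxcar per regulation block (n_retained x 4)."""
    hrf = hrf or build_chrf(tr=design.tr)
    dt = hrf.dt
    n_fine = round(design.n_retained * design.tr / dt)
    t = np.arange(n_fine) * dt
    sub = round(design.tr / dt)
    cols = []
    for onset, dur in design.regulation_blocks():
        box = ((t >= onset) & (t < onset + dur)).astype(float)
        conv = convolve_causal(box, hrf.kernel_dt, step=dt)
        cols.append(conv[sub - 1 :: sub][: design.n_retained])
    return np.column_stack(cols)


def extract_block_betas(
    processed_amy_series: np.ndarray,
    design: BlockDesign,
    hrf: CanonicalHrf | None = None,
    motion: np.ndarray | None = None,
) -> np.ndarray:
    """Per-regulation-block amygdala amplitudes from a block-wise GLM.

    The model has one convolved boxcar per regulation block plus an
    intercept; motion columns are excluded by default (the processed
    feedback series is already cleaned) but can be supplied.
    """
    y = np.asarray(processed_amy_series, float)
    regs = block_regressors(design, hrf)
    if regs.shape[1] != 4 and len(design.regulation_blocks()) != regs.shape[1]:
        raise ValueError("missing regulation blocks in design")
    parts = [regs, np.ones((y.size, 1))]
    if motion is not None:
        parts.insert(1, np.asarray(motion, float))
    X = np.column_stack(parts)
    if y.size != X.shape[0]:
        raise ValueError("series length does not match the design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[: regs.shape[1]]


def block_beta_table(dataset) -> pd.DataFrame:
    """BlockBetaTable: participant x run x block amygdala betas.

    Uses the Kalman-processed (despiked) online amygdala series, matching
    what the feedback loop itself consumed.
    """
    hrf = build_chrf(tr=dataset.config.tr)
    rows = []
    for p in dataset.participants:
        for rec in p.runs:
            betas = extract_block_betas(rec.despiked, rec.design, hrf)
            for b, beta in enumerate(betas, start=1):
                rows.append(
                    {
                        "participant_id": p.id,
                        "group": p.group.name,
                        "congruent": p.group.congruent,
                        "run": rec.run_index,
                        "block": b,
                        "beta": float(beta),
                    }
                )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- habituation


def habituation_slope(block_betas: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) of the least-squares line over block index 1..4."""
    b = np.asarray(block_betas, float)
    if b.size != 4:
        raise ValueError(f"expected 4 block betas, got {b.size}")
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite block betas")
    x = np.arange(1, 5, dtype=float)
    slope, intercept = np.polyfit(x, b, 1)
    return float(slope), float(intercept)


def habituation_table(betas: pd.DataFrame) -> pd.DataFrame:
    """HabituationSlopes: one within-run slope per participant x run."""
    rows = []
    for (pid, group, run), sub in betas.groupby(
        ["participant_id", "group", "run"], sort=True
    ):
        ordered = sub.sort_values("block")["beta"].to_numpy()
        slope, intercept = habituation_slope(ordered)
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "run": run,
                "slope": slope,
                "intercept": intercept,
            }
        )
    return pd.DataFrame(rows)


def orthogonality_report(dm: DesignMatrix) -> dict:
    """Correlations certifying the x3 orthogonalization contract."""
    f = dm.frame
    x1, x2, x3 = (f["x1_task"], f["x2_nf_response"], f["x3_nf_signal"])

    def _corr(a, b):
        a = a - np.mean(a)
        b = b - np.mean(b)
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / denom) if denom > 0 else 0.0

    return {
        "corr_x3_x1": _corr(x3, x1),
        "corr_x3_x2": _corr(x3, x2),
        "corr_x1_x2": _corr(x1, x2),
    }
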