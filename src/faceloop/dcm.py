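"""Bilinear effective-connectivity modelling (reduced DCM) with BMA.

The network is fixed to four regions (V1, FFA, Amy, mOFC). Candidate
directed connections are the three forward edges from V1 plus the two
bidirectional pairs FFA<->Amy and mOFC<->Amy; self-connections are always
present and V1 always receives the driving input. Enumerating every on/off
combination of the 7 optional edges yields the 2^7 = 128-model space.

Each model is a one-state bilinear DCM: neural dynamics

    dz/dt = (A + u_face B_face + u_int B_int) z + C [u_face, u_int]'

observed through convolution with the canonical HRF and sampled at TR
(no balloon model; hemodynamics are not estimated). Inversion is MAP
estimation under independent Gaussian priors via Gauss-Newton /
Levenberg-Marquardt steps with a Laplace approximation to the log model
evidence (free energy F = accuracy - complexity). Group inference uses
Bayesian model averaging: per-subject posterior model weights are the
softmax of F under a uniform model prior, and group-level weights average
the subject posteriors (a documented simplification of the Dirichlet
random-effects scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .cohort import (
    CANDIDATE_EDGES,
    N_REGIONS,
    REGIONS,
    NeuralParams,
    UnstableParametersError,
)
from .hrf import CanonicalHrf, build_chrf

N_OPTIONAL_EDGES = len(CANDIDATE_EDGES)  # 7

# priors (SPM-like scales)
PRIOR_SELF_MEAN = -0.5
PRIOR_SELF_VAR = 0.0625
PRIOR_EDGE_VAR = 0.25
PRIOR_C_VAR = 1.0


@dataclass(frozen=True)
class DcmModelSpec:
    """One member of the model space: a 7-bit mask over CANDIDATE_EDGES.

    The modulation masks (B_face, B_int) are tied to the A mask: an edge
    that exists may be modulated by both inputs.
    """

    model_id: int
    edge_mask: tuple  # 7 bools, ordered as CANDIDATE_EDGES

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [e for e, on in zip(CANDIDATE_EDGES, self.edge_mask) if on]

    @property
    def n_edges(self) -> int:
        return sum(self.edge_mask)


def enumerate_model_space() -> list[DcmModelSpec]:
    """All 128 on/off combinations of the 7 optional connections."""
    models = []
    for mid in range(2**N_OPTIONAL_EDGES):
        mask = tuple(bool((mid >> b) & 1) for b in range(N_OPTIONAL_EDGES))
        models.append(DcmModelSpec(model_id=mid, edge_mask=mask))
    return models


def reduced_model_space(n: int) -> list[DcmModelSpec]:
    """Deterministic n-model subset: the densest models first (the full
    model is always included), ties broken by model id."""
    space = enumerate_model_space()
    if not 1 <= n <= len(space):
        raise ValueError(f"reduced space size {n} outside 1..{len(space)}")
    ranked = sorted(space, key=lambda m: (-m.n_edges, m.model_id))
    return ranked[:n]


def model_space_manifest(models: list[DcmModelSpec]) -> pd.DataFrame:
    rows = []
    for m in models:
        row = {"model_id": m.model_id, "n_edges": m.n_edges}
        for (src, dst), on in zip(CANDIDATE_EDGES, m.edge_mask):
            row[f"{src}->{dst}"] = int(on)
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------- parameter layout


@dataclass(frozen=True)
class _ParamLayout:
    """Index bookkeeping for a model's free-parameter vector."""

    spec: DcmModelSpec
    names: tuple
    prior_mean: np.ndarray
    prior_var: np.ndarray

    @classmethod
    def for_spec(cls, spec: DcmModelSpec) -> "_ParamLayout":
        names, mu, var = [], [], []
        for r in REGIONS:  # self connections, always free
            names.append(f"A:{r}->{r}")
            mu.append(PRIOR_SELF_MEAN)
            var.append(PRIOR_SELF_VAR)
        for src, dst in spec.edges:
            names.append(f"A:{src}->{dst}")
            mu.append(0.0)
            var.append(PRIOR_EDGE_VAR)
        for src, dst in spec.edges:
            names.append(f"Bface:{src}->{dst}")
            mu.append(0.0)
            var.append(PRIOR_EDGE_VAR)
        for src, dst in spec.edges:
            names.append(f"Bint:{src}->{dst}")
            mu.append(0.0)
            var.append(PRIOR_EDGE_VAR)
        names += ["C:face->V1", "C:int->V1"]
        mu += [0.0, 0.0]
        var += [PRIOR_C_VAR, PRIOR_C_VAR]
        return cls(
            spec=spec,
            names=tuple(names),
            prior_mean=np.array(mu),
            prior_var=np.array(var),
        )

    def to_matrices(self, theta: np.ndarray) -> NeuralParams:
        A = np.zeros((N_REGIONS, N_REGIONS))
        Bf = np.zeros((N_REGIONS, N_REGIONS))
        Bi = np.zeros((N_REGIONS, N_REGIONS))
        C = np.zeros((N_REGIONS, 2))
        k = 0
        for r in range(N_REGIONS):
            A[r, r] = theta[k]
            k += 1
        ne = self.spec.n_edges
        for j, (src, dst) in enumerate(self.spec.edges):
            A[REGIONS.index(dst), REGIONS.index(src)] = theta[k + j]
        k += ne
        for j, (src, dst) in enumerate(self.spec.edges):
            Bf[REGIONS.index(dst), REGIONS.index(src)] = theta[k + j]
        k += ne
        for j, (src, dst) in enumerate(self.spec.edges):
            Bi[REGIONS.index(dst), REGIONS.index(src)] = theta[k + j]
        k += ne
        C[0, 0], C[0, 1] = theta[k], theta[k + 1]
        return NeuralParams(A=A, B_face=Bf, B_int=Bi, C=C, validate=False)

    def to_batched(self, theta: np.ndarray):
        """(A, Bf, Bi, C) stacks for a batch of parameter vectors
        (theta shape (batch, P))."""
        theta = np.atleast_2d(theta)
        B = theta.shape[0]
        A = np.zeros((B, N_REGIONS, N_REGIONS))
        Bf = np.zeros((B, N_REGIONS, N_REGIONS))
        Bi = np.zeros((B, N_REGIONS, N_REGIONS))
        C = np.zeros((B, N_REGIONS, 2))
        k = 0
        for r in range(N_REGIONS):
            A[:, r, r] = theta[:, k]
            k += 1
        ne = self.spec.n_edges
        for j, (src, dst) in enumerate(self.spec.edges):
            A[:, REGIONS.index(dst), REGIONS.index(src)] = theta[:, k + j]
        k += ne
        for j, (src, dst) in enumerate(self.spec.edges):
            Bf[:, REGIONS.index(dst), REGIONS.index(src)] = theta[:, k + j]
        k += ne
        for j, (src, dst) in enumerate(self.spec.edges):
            Bi[:, REGIONS.index(dst), REGIONS.index(src)] = theta[:, k + j]
        k += ne
        C[:, 0, 0], C[:, 0, 1] = theta[:, k], theta[:, k + 1]
        return A, Bf, Bi, C


# -------------------------------------------------------------- forward model


def dcm_predict(
    params: NeuralParams,
    face_input: np.ndarray,
    intensity_input: np.ndarray,
    hrf: CanonicalHrf,
    tr: float,
    dt: float | None = None,
) -> np.ndarray:
    """Noiseless predicted BOLD (n_volumes x 4) for given inputs at dt."""
    from .cohort import hemodynamic_observe, integrate_neural

    dt = hrf.dt if dt is None else dt
    z = integrate_neural(params, face_input, intensity_input, dt)
    return hemodynamic_observe(z, hrf, tr, dt=dt)


def _batched_predict(
    layout: _ParamLayout,
    thetas: np.ndarray,
    uf: np.ndarray,
    ui: np.ndarray,
    hrf: CanonicalHrf,
    tr: float,
    dt: float,
    divergence_bound: float = 1e4,
) -> np.ndarray:
    """Predicted BOLD for a batch of parameter vectors in one time sweep.

    Inputs are piecewise constant per TR, so the batch of 4x4 Jacobians is
    rebuilt once per volume, not per integration step.
    """
    A, Bf, Bi, C = layout.to_batched(thetas)
    B = A.shape[0]
    n_steps = uf.size
    sub = round(tr / dt)
    n_vol = n_steps // sub
    Z = np.zeros((B, N_REGIONS))
    traj = np.empty((n_steps, B, N_REGIONS))
    for v in range(n_vol):
        k0 = v * sub
        J = A + uf[k0] * Bf + ui[k0] * Bi
        drive = C @ np.array([uf[k0], ui[k0]])
        for s in range(sub):
            F0 = np.einsum("bij,bj->bi", J, Z) + drive
            F1 = np.einsum("bij,bj->bi", J, Z + dt * F0) + drive
            Z = Z + 0.5 * dt * (F0 + F1)
            traj[k0 + s] = Z
        if np.any(np.abs(Z) > divergence_bound):
            raise UnstableParametersError("batched DCM prediction diverged")
    kernel = hrf.kernel_dt[:, None, None]
    conv = fftconvolve(traj, kernel, axes=0)[:n_steps] * dt
    idx = np.arange(sub - 1, n_steps, sub)
    return conv[idx]  # (n_vol, B, 4)


# ------------------------------------------------------------ model / results


@dataclass
class DCMFit:
    """Posterior of one model for one subject's run."""

    spec: DcmModelSpec
    names: tuple
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    prior_penalty: float
    explained_variance: float
    sigma2: np.ndarray
    converged: bool
    n_iter: int

    @property
    def params(self) -> NeuralParams:
        return _ParamLayout.for_spec(self.spec).to_matrices(self.posterior_mean)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": list(self.names),
                "posterior_mean": self.posterior_mean,
                "posterior_sd": np.sqrt(np.diag(self.posterior_cov)),
            }
        )


class BilinearDCM:
    """MAP inversion of one bilinear DCM on a 4-region BOLD series.

    Parameters
    ----------
    data : array (n_volumes, 4)
        ROI BOLD series, region order V1, FFA, Amy, mOFC.
    face_input, intensity_input : arrays on the dt grid
        Driving face boxcar and displayed-intensity series.
    spec : DcmModelSpec
        Which optional edges exist (self-connections and V1 input implied).
    """

    def __init__(
        self,
        data: np.ndarray,
        face_input: np.ndarray,
        intensity_input: np.ndarray,
        spec: DcmModelSpec,
        tr: float = 1.0,
        dt: float = 0.1,
        hrf: CanonicalHrf | None = None,
    ):
        self.data = np.asarray(data, float)
        self.uf = np.asarray(face_input, float)
        self.ui = np.asarray(intensity_input, float)
        if self.uf.shape != self.ui.shape:
            raise ValueError("face and intensity inputs must share the dt grid")
        sub = round(tr / dt)
        if self.uf.size != self.data.shape[0] * sub:
            raise ValueError(
                "inputs not aligned with the data: expected "
                f"{self.data.shape[0] * sub} dt samples, got {self.uf.size}"
            )
        self.spec = spec
        self.tr, self.dt = tr, dt
        self.hrf = hrf or build_chrf(tr=tr, dt=dt)
        self.layout = _ParamLayout.for_spec(spec)

    # ------------------------------------------------------------------- fit
    def fit(self, max_iter: int = 32, tol: float = 1e-4) -> DCMFit:
        lay = self.layout
        theta = lay.prior_mean.copy()
        Pi = np.diag(1.0 / lay.prior_var)
        y = self.data
        n_vol, n_reg = y.shape
        sigma2 = np.maximum(y.var(axis=0), 1e-4)
        eps = 1e-4
        lam = 1.0
        P = theta.size

        def objective(pred, th, s2):
            r = y - pred
            e = th - lay.prior_mean
            return 0.5 * np.sum(r**2 / s2) + 0.5 * e @ Pi @ e

        pred = self._predict_batch(theta[None])[:, 0, :]
        obj = objective(pred, theta, sigma2)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # batched forward differences: rows = [theta, theta + eps e_j]
            batch = np.vstack([theta[None], theta[None] + eps * np.eye(P)])
            preds = self._predict_batch(batch)  # (n_vol, P+1, 4)
            pred0 = preds[:, 0, :]
            jac = (preds[:, 1:, :] - pred0[:, None, :]) / eps  # (n_vol, P, 4)
            # update noise estimate, then take a damped GN step
            resid = y - pred0
            sigma2 = np.maximum((resid**2).mean(axis=0), 1e-6)
            W = 1.0 / sigma2
            Jw = jac * W[None, None, :]
            H = np.einsum("tpr,tqr->pq", Jw, jac) + Pi
            g = np.einsum("tpr,tr->p", Jw, resid) - Pi @ (theta - lay.prior_mean)
            obj = objective(pred0, theta, sigma2)
            accepted = False
            for _ in range(8):
                try:
                    delta = np.linalg.solve(H + lam * np.diag(np.diag(H)), g)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                cand = theta + delta
                try:
                    pred_c = self._predict_batch(cand[None])[:, 0, :]
                except UnstableParametersError:
                    lam *= 10
                    continue
                obj_c = objective(pred_c, cand, sigma2)
                if obj_c < obj:
                    accepted = True
                    step = float(np.max(np.abs(delta)))
                    theta, pred, obj = cand, pred_c, obj_c
                    lam = max(lam / 3, 1e-6)
                    break
                lam *= 10
            if not accepted:
                converged = True  # no admissible descent direction left
                break
            if step < tol:
                converged = True
                break

        # Laplace free energy at the MAP estimate
        batch = np.vstack([theta[None], theta[None] + eps * np.eye(P)])
        preds = self._predict_batch(batch)
        pred0 = preds[:, 0, :]
        jac = (preds[:, 1:, :] - pred0[:, None, :]) / eps
        resid = y - pred0
        sigma2 = np.maximum((resid**2).mean(axis=0), 1e-6)
        W = 1.0 / sigma2
        Jw = jac * W[None, None, :]
        H = np.einsum("tpr,tqr->pq", Jw, jac) + Pi
        e = theta - lay.prior_mean
        accuracy = float(
            -0.5 * np.sum(resid**2 / sigma2)
            - 0.5 * n_vol * np.sum(np.log(2 * np.pi * sigma2))
        )
        prior_penalty = float(0.5 * e @ Pi @ e)
        sign, logdet_H = np.linalg.slogdet(H)
        logdet_Pi = float(np.sum(np.log(np.diag(Pi))))
        occam = 0.5 * (logdet_H - logdet_Pi)
        complexity = prior_penalty + occam
        F = accuracy - complexity
        cov = np.linalg.inv(H)
        ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
        ev = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        return DCMFit(
            spec=self.spec,
            names=lay.names,
            posterior_mean=theta,
            posterior_cov=cov,
            free_energy=float(F),
            accuracy=accuracy,
            complexity=float(complexity),
            prior_penalty=prior_penalty,
            explained_variance=ev,
            sigma2=sigma2,
            converged=converged,
            n_iter=it,
        )

    def _predict_batch(self, thetas: np.ndarray) -> np.ndarray:
        return _batched_predict(
            self.layout, thetas, self.uf, self.ui, self.hrf, self.tr, self.dt
        )


def invert_dcm(
    spec: DcmModelSpec,
    data: np.ndarray,
    face_input: np.ndarray,
    intensity_input: np.ndarray,
    tr: float = 1.0,
    dt: float = 0.1,
    **fit_kw,
) -> DCMFit:
    """Convenience wrapper: build the model and fit."""
    return BilinearDCM(data, face_input, intensity_input, spec, tr=tr, dt=dt).fit(
        **fit_kw
    )


# ----------------------------------------------------------------------- BMA


def model_weights(free_energies: np.ndarray) -> np.ndarray:
    """Posterior model probabilities from per-subject free energies.

    ``free_energies`` is (n_subjects, n_models); each subject's weights are
    the softmax of F under a uniform model prior. Non-finite F values
    exclude the model for that subject (weight 0) with a warning.
    """
    import warnings

    F = np.atleast_2d(np.asarray(free_energies, float))
    W = np.zeros_like(F)
    for i, row in enumerate(F):
        ok = np.isfinite(row)
        if not ok.all():
            warnings.warn(
                f"subject {i}: {np.sum(~ok)} model(s) with non-finite F excluded",
                stacklevel=2,
            )
        if not ok.any():
            raise ValueError(f"subject {i}: no finite free energies")
        z = row[ok] - row[ok].max()
        w = np.exp(z)
        W[i, ok] = w / w.sum()
    return W


@dataclass
class BmaResult:
    """Model-averaged connectivity for a set of subjects (one run each)."""

    A: np.ndarray       # (n_subjects, 4, 4)
    B_face: np.ndarray
    B_int: np.ndarray
    C: np.ndarray       # (n_subjects, 4, 2)
    weights: np.ndarray  # (n_subjects, n_models)
    model_ids: tuple

    @property
    def total(self) -> np.ndarray:
        """Task-dependent connectivity: elementwise A + B_face + B_int."""
        return self.A + self.B_face + self.B_int

    def group_mean(self) -> dict:
        return {
            "A": self.A.mean(axis=0),
            "B_face": self.B_face.mean(axis=0),
            "B_int": self.B_int.mean(axis=0),
            "total": self.total.mean(axis=0),
        }

    def group_sd(self) -> dict:
        return {
            "A": self.A.std(axis=0, ddof=1),
            "B_face": self.B_face.std(axis=0, ddof=1),
            "B_int": self.B_int.std(axis=0, ddof=1),
            "total": self.total.std(axis=0, ddof=1),
        }

    def connection_table(self, group: str = "", run: int = 0) -> pd.DataFrame:
        """Per-connection summary mirroring a BMA results table:
        mean +/- between-subject SD for A, B1, B2 and the total."""
        mean, sd = self.group_mean(), self.group_sd()
        rows = []
        for src, dst in CANDIDATE_EDGES:
            i, j = REGIONS.index(dst), REGIONS.index(src)
            rows.append(
                {
                    "connection": f"{src}->{dst}",
                    "group": group,
                    "run": run,
                    "A": mean["A"][i, j],
                    "A_sd": sd["A"][i, j],
                    "B1_face": mean["B_face"][i, j],
                    "B1_sd": sd["B_face"][i, j],
                    "B2_intensity": mean["B_int"][i, j],
                    "B2_sd": sd["B_int"][i, j],
                    "total": mean["total"][i, j],
                    "total_sd": sd["total"][i, j],
                }
            )
        return pd.DataFrame(rows)


def bma(fits: list[list[DCMFit]], weights: np.ndarray | None = None) -> BmaResult:
    """Average posterior parameters over the model space.

    ``fits[s][m]`` is subject s's fit of model m; weights default to the
    softmax of the fits' free energies. Absent edges contribute 0.
    """
    F = np.array([[f.free_energy for f in row] for row in fits])
    if weights is None:
        weights = model_weights(F)
    weights = np.atleast_2d(weights)
    if weights.shape != F.shape:
        raise ValueError("weights shape does not match fits")
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("weights must sum to 1 per subject")
    n_subj = len(fits)
    A = np.zeros((n_subj, N_REGIONS, N_REGIONS))
    Bf = np.zeros_like(A)
    Bi = np.zeros_like(A)
    C = np.zeros((n_subj, N_REGIONS, 2))
    for s, row in enumerate(fits):
        for m, fit in enumerate(row):
            w = weights[s, m]
            if w == 0.0:
                continue
            p = fit.params
            A[s] += w * p.A
            Bf[s] += w * p.B_face
            Bi[s] += w * p.B_int
            C[s] += w * p.C
    return BmaResult(
        A=A,
        B_face=Bf,
        B_int=Bi,
        C=C,
        weights=weights,
        model_ids=tuple(f.spec.model_id for f in fits[0]),
    )


def edge_values(matrix: np.ndarray, src: str, dst: str) -> np.ndarray:
    """Extract one directed connection from stacked (n, 4, 4) matrices."""
    return matrix[..., REGIONS.index(dst), REGIONS.index(src)]
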