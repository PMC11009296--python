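"""Variance-based global sensitivity analysis on the trained surrogate.

Scalar quantities of interest (per-chamber pressure/volume extrema plus
ventricular stroke volume and ejection fraction) are extracted from each
predicted cycle.  Parameter samples follow the Saltelli radial design
built on a scrambled Sobol' low-discrepancy sequence; first-order indices
use the Saltelli (2010) estimator and total-effect indices the Jansen
estimator, with bootstrap confidence half-widths over base rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .lnode import N_PHYSICAL, TrainedSurrogate, integrate_scaled
from .parameters import ParameterSpace
from .traces import CHANNELS, PVTrace

__all__ = [
    "QOI_NAMES",
    "QoIVector",
    "SobolIndices",
    "extract_qois",
    "saltelli_sample",
    "sobol_indices",
    "rank_relevant",
    "gsa_pipeline",
]

logger = logging.getLogger(__name__)

QOI_NAMES = tuple(
    [f"max_{c}" for c in CHANNELS]
    + [f"min_{c}" for c in CHANNELS]
    + ["SV_LV", "SV_RV", "EF_LV", "EF_RV"]
)


@dataclass(frozen=True)
class QoIVector:
    """The 20 scalar quantities of interest of one cardiac cycle."""

    values: np.ndarray  # aligned with QOI_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[QOI_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(QOI_NAMES, self.values)}


def _qois_from_matrix(values: np.ndarray) -> np.ndarray:
    """QoIs for stacked cycles ``(..., n_samples, 8)`` -> ``(..., 20)``."""
    vmax = values.max(axis=-2)
    vmin = values.min(axis=-2)
    iV_LV, iV_RV = CHANNELS.index("V_LV"), CHANNELS.index("V_RV")
    sv_lv = vmax[..., iV_LV] - vmin[..., iV_LV]
    sv_rv = vmax[..., iV_RV] - vmin[..., iV_RV]
    ef_lv = sv_lv / vmax[..., iV_LV]
    ef_rv = sv_rv / vmax[..., iV_RV]
    return np.concatenate(
        [vmax, vmin, np.stack([sv_lv, sv_rv, ef_lv, ef_rv], axis=-1)], axis=-1
    )


def extract_qois(trace: PVTrace) -> QoIVector:
    """Grid extrema per channel plus ventricular SV and EF."""
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("trace contains non-finite values")
    return QoIVector(_qois_from_matrix(trace.values))


@dataclass(frozen=True)
class SobolIndices:
    """First-order and total-effect index matrices, QoI x parameter."""

    S1: np.ndarray
    ST: np.ndarray
    qoi_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    n_base: int
    ci_S1: np.ndarray | None = None
    ci_ST: np.ndarray | None = None
    S2: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (qoi, parameter)."""
        rows = []
        for qi, q in enumerate(self.qoi_names):
            for pi, p in enumerate(self.parameter_names):
                rows.append({
                    "qoi": q, "parameter": p,
                    "S1": self.S1[qi, pi], "ST": self.ST[qi, pi],
                    "ci_S1": self.ci_S1[qi, pi] if self.ci_S1 is not None else np.nan,
                    "ci_ST": self.ci_ST[qi, pi] if self.ci_ST is not None else np.nan,
                })
        return pd.DataFrame(rows)

    def heatmap_table(self) -> pd.DataFrame:
        """QoI x parameter matrix of total-effect indices."""
        return pd.DataFrame(self.ST, index=list(self.qoi_names),
                            columns=list(self.parameter_names))

    def plot_heatmap(self, path=None, which: str = "ST"):
        """Render the QoI x parameter index matrix as a heatmap.

        Requires matplotlib (the ``plot`` extra); returns the figure, and
        saves it to ``path`` when given.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = self.ST if which == "ST" else self.S1
        fig, ax = plt.subplots(
            figsize=(1 + 0.45 * len(self.parameter_names),
                     1 + 0.3 * len(self.qoi_names)))
        im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(self.parameter_names)),
                      self.parameter_names, rotation=90)
        ax.set_yticks(range(len(self.qoi_names)), self.qoi_names)
        fig.colorbar(im, ax=ax, label=f"{which} Sobol index")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig


def saltelli_design_size(P: int, n_base: int, second_order: bool = False) -> int:
    """Number of model evaluations the Saltelli design requires:
    ``n_base * (2P + 2)`` with second-order blocks, ``n_base * (P + 2)``
    without."""
    return n_base * (2 * P + 2 if second_order else P + 2)


def saltelli_sample(
    space: ParameterSpace, n_base: int, second_order: bool = False, seed: int = 0
) -> np.ndarray:
    """Saltelli design over the box: ``n_base*(2P+2)`` rows with second-order
    blocks, ``n_base*(P+2)`` without.

    Row layout: the ``A`` block, the ``B`` block, the ``P`` radial blocks
    ``AB_i`` (A with column i from B) and, when ``second_order`` is on, the
    ``P`` blocks ``BA_i``.  Base matrices come from a seeded scrambled
    Sobol' sequence, so the design is reproducible.
    """
    P = len(space)
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    if n_base & (n_base - 1):
        warnings.warn("n_base is not a power of 2; Sobol' balance degrades",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sob = qmc.Sobol(d=2 * P, scramble=True, seed=int(seed))
        base = sob.random(n_base)
    A = qmc.scale(base[:, :P], space.lower, space.upper)
    B = qmc.scale(base[:, P:], space.lower, space.upper)
    blocks = [A, B]
    for i in range(P):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    if second_order:
        for i in range(P):
            BA = B.copy()
            BA[:, i] = A[:, i]
            blocks.append(BA)
    return np.vstack(blocks)


def _split_blocks(evaluations: np.ndarray, P: int, n_base: int, second_order: bool):
    n_blocks = 2 * P + 2 if second_order else P + 2
    if evaluations.shape[0] != n_blocks * n_base:
        raise ValueError(
            f"got {evaluations.shape[0]} evaluations, expected {n_blocks * n_base}"
        )
    ev = evaluations.reshape(n_blocks, n_base, -1)
    fA, fB = ev[0], ev[1]
    fAB = ev[2:2 + P]
    fBA = ev[2 + P:] if second_order else None
    return fA, fB, fAB, fBA


def _estimators(fA, fB, fAB, fBA):
    """Saltelli-2010 S1 and Jansen ST for one bootstrap replicate."""
    allf = np.concatenate([fA, fB], axis=0)
    V = allf.var(axis=0, ddof=0)
    V = np.where(V <= 0, np.nan, V)
    S1 = np.stack([(fB * (fAB[i] - fA)).mean(axis=0) / V for i in range(len(fAB))])
    ST = np.stack([0.5 * ((fA - fAB[i]) ** 2).mean(axis=0) / V for i in range(len(fAB))])
    S2 = None
    if fBA is not None:
        P = len(fAB)
        S2 = np.full((P, P, fA.shape[1]), np.nan)
        for i in range(P):
            for j in range(i + 1, P):
                Vij = (fBA[i] * fAB[j]).mean(axis=0) - (fA * fB).mean(axis=0)
                S2[i, j] = S2[j, i] = Vij / V - S1[i] - S1[j]
    return S1, ST, S2


def sobol_indices(
    evaluations: np.ndarray,
    P: int,
    n_base: int,
    second_order: bool = False,
    qoi_names=None,
    parameter_names=None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> SobolIndices:
    """Estimate Sobol indices from evaluations aligned with the design.

    ``evaluations`` has one row per design row and one column per QoI.
    Rows with NaN evaluations are dropped pairwise across blocks (the same
    base index is removed from every block) with a logged count.  Bootstrap
    half-widths (95%) are computed over resampled base rows.
    """
    evaluations = np.atleast_2d(np.asarray(evaluations, float))
    if evaluations.shape[0] == 1 and evaluations.shape[1] != 1:
        evaluations = evaluations.T
    fA, fB, fAB, fBA = _split_blocks(evaluations, P, n_base, second_order)
    stack = [fA, fB] + list(fAB) + (list(fBA) if fBA is not None else [])
    ok = np.all([np.all(np.isfinite(b), axis=1) for b in stack], axis=0)
    if not ok.all():
        logger.warning("dropping %d of %d base rows with NaN evaluations",
                       (~ok).sum(), n_base)
        fA, fB = fA[ok], fB[ok]
        fAB = fAB[:, ok]
        fBA = fBA[:, ok] if fBA is not None else None
    n_eff = fA.shape[0]

    S1, ST, S2 = _estimators(fA, fB, fAB, fBA)
    rng = np.random.default_rng(int(seed))
    if n_bootstrap > 0:
        bs1, bst = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_eff, n_eff)
            s1b, stb, _ = _estimators(fA[idx], fB[idx], fAB[:, idx], None)
            bs1.append(s1b)
            bst.append(stb)
        ci_S1 = 1.96 * np.std(bs1, axis=0).T
        ci_ST = 1.96 * np.std(bst, axis=0).T
    else:
        ci_S1 = ci_ST = None

    nq = fA.shape[1]
    qoi_names = tuple(qoi_names) if qoi_names else tuple(f"qoi_{i}" for i in range(nq))
    parameter_names = (tuple(parameter_names) if parameter_names
                       else tuple(f"x_{i}" for i in range(P)))
    return SobolIndices(
        S1=S1.T, ST=ST.T, qoi_names=qoi_names, parameter_names=parameter_names,
        n_base=n_eff, ci_S1=ci_S1, ci_ST=ci_ST,
        S2=None if S2 is None else np.moveaxis(S2, 2, 0),
    )


def rank_relevant(ix: SobolIndices, threshold: float = 0.1):
    """Parameters whose total-effect index exceeds ``threshold`` for >= 1 QoI.

    Returns ``(relevant_set, per_parameter_max)`` where the second item maps
    every parameter to its maximum total-effect index over QoIs.
    """
    with np.errstate(invalid="ignore"):
        mx = np.nanmax(ix.ST, axis=0)
    per_param = {p: float(m) for p, m in zip(ix.parameter_names, mx)}
    relevant = {p for p, m in per_param.items() if m > threshold}
    return relevant, per_param


def _surrogate_qois(model: TrainedSurrogate, thetas: np.ndarray,
                    z0_physical: np.ndarray, samples_per_beat: int = 200,
                    chunk: int = 4096) -> np.ndarray:
    """Vectorized surrogate evaluation of QoIs for a matrix of theta rows."""
    space = model.space
    n = thetas.shape[0]
    ref = {nm: space.reference[i] for i, nm in enumerate(space.names)}
    T_HB = (thetas[:, space.index("T_HB")] if "T_HB" in space
            else np.full(n, ref.get("T_HB", 0.8)))
    AV = (thetas[:, space.index("AV_delay")] if "AV_delay" in space
          else np.full(n, ref.get("AV_delay", 0.16)))
    z0s = model.scalers.scale(z0_physical)
    out = np.empty((n, len(QOI_NAMES)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        R = hi - lo
        theta_s = space.to_unit(thetas[lo:hi])
        Z0 = np.concatenate(
            [np.broadcast_to(z0s, (R, N_PHYSICAL)),
             np.broadcast_to(model.z0_latent, (R, model.config.n_latent))], axis=1
        )
        try:
            Z, _, _ = integrate_scaled(
                model.weights, Z0, theta_s, T_HB[lo:hi], AV[lo:hi],
                T_HB[lo:hi] / samples_per_beat, samples_per_beat,
            )
            phys = model.scalers.unscale(Z[:, :samples_per_beat, :N_PHYSICAL])
            out[lo:hi] = _qois_from_matrix(phys)
        except FloatingPointError:
            # fall back row by row so a single divergent draw only NaNs itself
            for r in range(lo, hi):
                try:
                    Z, _, _ = integrate_scaled(
                        model.weights,
                        np.concatenate([z0s, model.z0_latent])[None, :],
                        space.to_unit(thetas[r])[None, :], T_HB[r:r + 1],
                        AV[r:r + 1], T_HB[r:r + 1] / samples_per_beat,
                        samples_per_beat,
                    )
                    out[r] = _qois_from_matrix(
                        model.scalers.unscale(Z[0, :samples_per_beat, :N_PHYSICAL])
                    )
                except FloatingPointError:
                    out[r] = np.nan
    return out


def gsa_pipeline(
    model: TrainedSurrogate,
    space: ParameterSpace | None = None,
    n_base: int = 1024,
    second_order: bool = False,
    seed: int = 0,
    z0_physical: np.ndarray | None = None,
    n_bootstrap: int = 200,
) -> SobolIndices:
    """Saltelli-sample the space, evaluate the surrogate, estimate indices.

    ``z0_physical`` defaults to the training-set mean initial condition
    stored in the model scalers' center, held fixed across design rows so
    the indices isolate parameter-driven variance.
    """
    space = space or model.space
    if space.names != model.space.names:
        raise ValueError("GSA space must match the surrogate's parameter space")
    if z0_physical is None:
        z0_physical = np.asarray(
            model.meta.get("z0_mean", model.scalers.center), float
        )
    design = saltelli_sample(space, n_base, second_order, seed)
    evals = _surrogate_qois(model, design, z0_physical)
    return sobol_indices(
        evals, len(space), n_base, second_order,
        qoi_names=QOI_NAMES, parameter_names=space.names,
        n_bootstrap=n_bootstrap, seed=seed,
    )
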