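"""IBD-weighted regression QTL scans with permutation thresholds.

The trait is regressed on homolog-presence indicators
Y = mu' + a2 X2 + a3 X3 + a4 X4 + a6 X6 + a7 X7 + a8 X8 + e (tetraploid),
dropping X1 and X(ploidy+1) since per-parent indicators sum to ploidy/2.
Each individual is expanded into one pseudo-observation per ancestry state,
weighted by its posterior IBD probability; the fit is solved through the
weighted normal equations (never materializing the expansion).

LOD = (N/2) * log10(RSS0 / RSS1) with RSS0 the intercept-only residual sum
of squares on the unexpanded phenotypes.  Because posterior weights sum to 1
per individual, RSS1 <= RSS0 and LOD >= 0 always.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from polyqtl.ibd import HaplotypeProbs, IBDProbabilities, enumerate_ibd_states

__all__ = [
    "ScanModel",
    "QTLScanResult",
    "build_design",
    "weighted_lod",
    "lod_profiles",
    "scan",
    "permutation_maxima",
    "permutation_threshold",
    "support_interval",
    "interpolate_lod",
    "single_marker_scan",
    "allele_effects",
    "write_scan_tsv",
]


@dataclasses.dataclass
class ScanModel:
    """Design mapping ancestry states to homolog indicator values.

    ``X`` has one row per state; columns are the retained homolog terms
    (maternal 2..ploidy then paternal ploidy+2..2*ploidy).  noDR entries are
    0/1; DR entries may reach 2 (duplicated homolog inheritance).
    """

    ploidy: int
    model: str
    states: list
    X: np.ndarray  # (S, 2*(ploidy-1))
    terms: list[str]


def build_design(ploidy: int, model: str = "noDR") -> ScanModel:
    if ploidy not in (4, 6):
        raise ValueError("QTL scan supports ploidy 4 or 6")
    states = enumerate_ibd_states(ploidy, allow_dr=(model == "DR"))
    full = np.zeros((len(states), 2 * ploidy))
    for i, st in enumerate(states):
        for h in st.origins:
            full[i, h - 1] += 1.0
    keep = [j for j in range(2 * ploidy) if j not in (0, ploidy)]
    X = full[:, keep]
    terms = [f"X{j + 1}" for j in keep]
    # per-parent conservation: indicators (incl. the dropped term) sum to
    # ploidy/2 for every state
    assert np.allclose(full[:, :ploidy].sum(axis=1), ploidy / 2)
    assert np.allclose(full[:, ploidy:].sum(axis=1), ploidy / 2)
    return ScanModel(ploidy=ploidy, model=model, states=states, X=X, terms=terms)


def _wls_lod(
    Y: np.ndarray, W: np.ndarray, Z: np.ndarray, rss0: np.ndarray
) -> np.ndarray:
    """LOD for each phenotype column via weighted normal equations.

    Y : (N, P) phenotypes; W : (N, S) state weights (rows sum to 1);
    Z : (S, k) design incl. intercept; rss0 : (P,).
    """
    n = Y.shape[0]
    cw = W.sum(axis=0)  # (S,)
    M = Z.T @ (cw[:, None] * Z)  # (k, k)
    B = Z.T @ (W.T @ Y)  # (k, P)
    beta = np.linalg.pinv(M, rcond=1e-10) @ B  # minimum-norm under rank deficiency
    sum_y2 = (Y * Y).sum(axis=0)
    rss1 = np.maximum(sum_y2 - (B * beta).sum(axis=0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0 / np.maximum(rss1, 1e-300))
    lod = np.where(rss0 <= 0, 0.0, lod)
    return np.maximum(lod, 0.0)


def weighted_lod(
    y: np.ndarray, state_probs: np.ndarray, scan_model: ScanModel
) -> float:
    """LOD of the IBD-weighted homolog regression at a single locus.

    ``state_probs`` is the (N, S) posterior at the locus.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    rss0 = np.array([((y - y.mean()) ** 2).sum()])
    if rss0[0] <= 0:
        warnings.warn("zero phenotypic variance: LOD defined as 0", stacklevel=2)
        return 0.0
    W = np.asarray(state_probs, dtype=float)
    Z = np.column_stack([np.ones(W.shape[1]), scan_model.X])
    yc = y - y.mean()  # centering is affine-invariant for LOD; keeps M well-scaled
    return float(_wls_lod(yc[:, None], W, Z, rss0)[0])


def lod_profiles(
    Y: np.ndarray, ibd: IBDProbabilities, scan_model: ScanModel
) -> np.ndarray:
    """LOD matrix (loci x phenotype columns) for one or more phenotypes."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    rss0 = (Yc * Yc).sum(axis=0)
    Z = np.column_stack([np.ones(len(scan_model.states)), scan_model.X])
    L = ibd.probs.shape[1]
    out = np.empty((L, Y.shape[1]))
    for l in range(L):
        out[l] = _wls_lod(Yc, ibd.probs[:, l, :], Z, rss0)
    return out


@dataclasses.dataclass
class QTLScanResult:
    """LOD profile with peak, optional threshold and support intervals."""

    positions: np.ndarray
    lod: np.ndarray
    n: int
    model: str
    peak_position: float
    peak_lod: float
    peak_tied: bool = False
    threshold: float | None = None
    support_intervals: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_cM": self.positions, "LOD": self.lod})


def scan(
    y: np.ndarray, ibd: IBDProbabilities, scan_model: ScanModel
) -> QTLScanResult:
    """Chromosome-wide LOD scan at the grid positions of ``ibd``.

    Peak ties are broken leftmost and flagged.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) <= 0:
        warnings.warn("zero phenotypic variance: all-zero LOD profile", stacklevel=2)
        lod = np.zeros(ibd.probs.shape[1])
    else:
        lod = lod_profiles(y, ibd, scan_model)[:, 0]
    peak_idx = int(np.argmax(lod))
    tied = bool(np.sum(lod >= lod[peak_idx] - 1e-12) > 1)
    result = QTLScanResult(
        positions=ibd.positions.copy(),
        lod=lod,
        n=len(y),
        model=scan_model.model,
        peak_position=float(ibd.positions[peak_idx]),
        peak_lod=float(lod[peak_idx]),
        peak_tied=tied,
    )
    for drop in (1.0, 2.0):
        result.support_intervals[drop] = support_interval(
            ibd.positions, lod, drop
        )
    return result


def permutation_maxima(
    y: np.ndarray,
    ibd: IBDProbabilities,
    scan_model: ScanModel,
    n_perm: int,
    seed=None,
) -> np.ndarray:
    """Chromosome-wide maximum LOD for ``n_perm`` phenotype permutations."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lod = lod_profiles(Y, ibd, scan_model)
    return lod.max(axis=0)


def empirical_threshold(maxima: np.ndarray, alpha: float) -> float:
    """(1 - alpha) quantile of the sorted maxima: the ceil((1-alpha)*n)-th
    order statistic (inverse-ECDF rule)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    maxima = np.asarray(maxima, dtype=float)
    return float(np.quantile(maxima, 1.0 - alpha, method="inverted_cdf"))


def permutation_threshold(
    y: np.ndarray,
    ibd: IBDProbabilities,
    scan_model: ScanModel,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Experiment-wise LOD threshold from phenotype permutations."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maxima = permutation_maxima(y, ibd, scan_model, n_perm, seed)
    return empirical_threshold(maxima, alpha)


def support_interval(
    positions: np.ndarray, lod: np.ndarray, drop: float
) -> tuple[float, float]:
    """LOD-drop support interval: the full range of positions whose LOD is
    within ``drop`` of the maximum."""
    positions = np.asarray(positions, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if len(lod) == 0:
        raise ValueError("empty LOD profile")
    sel = lod > lod.max() - drop
    pos = positions[sel]
    return float(pos.min()), float(pos.max())


def interpolate_lod(positions, lod, position: float) -> float:
    """Linear interpolation of a LOD profile at an off-grid position."""
    positions = np.asarray(positions, dtype=float)
    if position < positions.min() - 1e-9 or position > positions.max() + 1e-9:
        raise ValueError("position outside the scanned span")
    return float(np.interp(position, positions, np.asarray(lod, dtype=float)))


def single_marker_scan(y: np.ndarray, dosages) -> np.ndarray:
    """Single-marker ANOVA baseline: regress y on raw dosage per marker.

    Missing dosages are dropped per marker; LOD uses the per-marker N.
    Monomorphic markers get LOD 0; all-missing markers get NaN (warned).
    """
    from polyqtl.meiosis import DosageMatrix

    values = dosages.values if isinstance(dosages, DosageMatrix) else np.asarray(
        dosages, dtype=float
    )
    y = np.asarray(y, dtype=float)
    m = values.shape[0]
    lod = np.zeros(m)
    n_all_missing = 0
    for mk in range(m):
        d = values[mk]
        keep = ~np.isnan(d)
        nk = int(keep.sum())
        if nk == 0:
            lod[mk] = np.nan
            n_all_missing += 1
            continue
        dk, yk = d[keep], y[keep]
        rss0 = ((yk - yk.mean()) ** 2).sum()
        if rss0 <= 0 or np.var(dk) <= 0:
            continue
        slope, intercept = np.polyfit(dk, yk, 1)
        rss1 = ((yk - slope * dk - intercept) ** 2).sum()
        lod[mk] = max(0.5 * nk * np.log10(rss0 / max(rss1, 1e-300)), 0.0)
    if n_all_missing:
        warnings.warn(
            f"{n_all_missing} marker(s) with all-missing dosages excluded",
            stacklevel=2,
        )
    return lod


def allele_effects(
    y: np.ndarray, hap: HaplotypeProbs, positions=None
) -> np.ndarray:
    """Average allele effect per homolog: hbar - ybar, with hbar the
    pi-weighted mean phenotype (noDR haplotypic probabilities).

    Returns an array (len(positions), 2*ploidy); entries where the total
    weight is zero are NaN.
    """
    if hap.model != "noDR":
        raise ValueError("allele effects are defined for noDR haplotype probs")
    y = np.asarray(y, dtype=float)
    if positions is None:
        idx = np.arange(len(hap.positions))
    else:
        idx = np.array(
            [int(np.argmin(np.abs(hap.positions - p))) for p in np.atleast_1d(positions)]
        )
    pi = hap.pi[:, idx, :]  # (N, P, 2p)
    tot = pi.sum(axis=0)  # (P, 2p)
    num = np.tensordot(y, pi, axes=([0], [0]))  # (P, 2p)
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = num / tot - y.mean()
    eff[tot <= 0] = np.nan
    return eff


def write_scan_tsv(result: QTLScanResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
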