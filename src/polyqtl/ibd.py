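"""Multipoint IBD (ancestry) estimation for autopolyploid F1 offspring.

Offspring ancestry at a locus is the pair of multisets of parental homologs
inherited from each parent.  Under the bivalent-only model ("noDR") each
parent contributes ploidy/2 *distinct* homologs: C(4,2)^2 = 36 states in a
tetraploid.  Allowing double reduction ("DR") adds duplicated-homolog
multisets: 10^2 = 100 tetraploid states (64 extra).

A hidden Markov model over these states is evaluated by the forward-backward
algorithm.  Transitions factorize over parents and chromatids: each inherited
chromatid origin persists over a map distance d with probability 1 - r and
moves to each other homolog with probability r / (ploidy - 1), where r is the
Haldane recombination fraction.  Under noDR the kernel is restricted to
distinct-index states and renormalized; under DR duplicated-index target
states are down-weighted by the multivalent rate q.

Emissions compare the observed SNP dosage with the dosage implied by the
state and the phased parental alleles, with a scalar genotyping error eps.
Posteriors at marker positions can be re-expressed on a 1 cM grid for QTL
scanning (cubic smoothing splines, clipped and renormalized).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, make_smoothing_spline

from polyqtl.maps import PhasedMap
from polyqtl.meiosis import DosageMatrix

__all__ = [
    "AncestryState",
    "IBDProbabilities",
    "HaplotypeProbs",
    "enumerate_ibd_states",
    "parent_states",
    "haldane",
    "parent_transition",
    "transition_matrix",
    "emission_prob",
    "ibd_posterior",
    "haplotype_probs",
    "spline_to_grid",
    "write_ibd_tsv",
]

_MODELS = ("noDR", "DR")


@dataclasses.dataclass(frozen=True)
class AncestryState:
    """One combination of inherited parental homologs at a locus.

    ``maternal`` holds sorted homolog indices in 1..ploidy, ``paternal`` in
    ploidy+1..2*ploidy (global numbering).  ``dr`` is True when either
    multiset contains a duplicated index (a double-reduction genotype).
    """

    maternal: tuple[int, ...]
    paternal: tuple[int, ...]

    @property
    def dr(self) -> bool:
        return len(set(self.maternal)) < len(self.maternal) or len(
            set(self.paternal)
        ) < len(self.paternal)

    @property
    def origins(self) -> tuple[int, ...]:
        return self.maternal + self.paternal

    def __str__(self) -> str:
        return "{%s}x{%s}" % (
            ",".join(map(str, self.maternal)),
            ",".join(map(str, self.paternal)),
        )


def _check_model(model: str) -> bool:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    return model == "DR"


@lru_cache(maxsize=None)
def parent_states(ploidy: int, allow_dr: bool) -> tuple[tuple[int, ...], ...]:
    """Ordered state space for one parent (homolog indices 1..ploidy)."""
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    half = ploidy // 2
    it = (
        itertools.combinations_with_replacement(range(1, ploidy + 1), half)
        if allow_dr
        else itertools.combinations(range(1, ploidy + 1), half)
    )
    return tuple(it)


def enumerate_ibd_states(ploidy: int, allow_dr: bool) -> list[AncestryState]:
    """Joint state space, maternal-major ordering.

    noDR count = C(ploidy, ploidy/2)^2; DR count = M^2 with M the number of
    multisets of size ploidy/2 from ploidy homologs (36 and 100 at ploidy 4).
    """
    ps = parent_states(ploidy, allow_dr)
    return [
        AncestryState(m, tuple(ploidy + h for h in p))
        for m in ps
        for p in ps
    ]


def haldane(d_cm: float) -> float:
    """Haldane map function: recombination fraction at distance d (cM)."""
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _multiset_kernel(ploidy: int, states, r: float) -> np.ndarray:
    """Chromatid-factorized transition kernel projected onto multisets."""
    p_stay = 1.0 - r
    p_move = r / (ploidy - 1)
    k = np.full((ploidy, ploidy), p_move)
    np.fill_diagonal(k, p_stay)
    s_arr = [np.asarray(s) - 1 for s in states]
    n = len(states)
    K = np.zeros((n, n))
    for j, t in enumerate(states):
        perms = set(itertools.permutations(t))
        for i, s in enumerate(s_arr):
            total = 0.0
            for perm in perms:
                prod = 1.0
                for a, b in zip(s, perm):
                    prod *= k[a, b - 1]
                total += prod
            K[i, j] = total
    return K


@lru_cache(maxsize=4096)
def _parent_kernel_cached(
    ploidy: int, allow_dr: bool, d_key: int, q: float
) -> np.ndarray:
    d_cm = d_key / 1e6
    states = parent_states(ploidy, allow_dr)
    K = _multiset_kernel(ploidy, states, haldane(d_cm))
    if allow_dr:
        w = np.array([1.0 if len(set(s)) == len(s) else q for s in states])
        K = K * w[None, :]
    row = K.sum(axis=1)
    dead = row <= 0
    if dead.any():  # e.g. duplicated source state at q = 0 and d = 0
        K[dead] = np.eye(len(states))[dead]
        row = K.sum(axis=1)
    K = K / row[:, None]
    return K


def parent_transition(
    ploidy: int, d_cm: float, model: str = "noDR", q: float = 0.0
) -> np.ndarray:
    """Row-stochastic per-parent transition kernel over parent states."""
    allow_dr = _check_model(model)
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    d_key = int(round(d_cm * 1e6))
    return _parent_kernel_cached(ploidy, allow_dr, d_key, float(q)).copy()


def transition_matrix(
    ploidy: int, d_cm: float, model: str = "noDR", q: float = 0.0
) -> np.ndarray:
    """Joint transition matrix over :func:`enumerate_ibd_states` ordering.

    Meioses of the two parents are independent, so the joint kernel is the
    Kronecker product of two per-parent kernels (maternal index major).
    """
    K = parent_transition(ploidy, d_cm, model, q)
    return np.kron(K, K)


def _parent_prior(ploidy: int, allow_dr: bool, q: float) -> np.ndarray:
    states = parent_states(ploidy, allow_dr)
    if not allow_dr:
        return np.full(len(states), 1.0 / len(states))
    w = np.array([1.0 if len(set(s)) == len(s) else q for s in states])
    if w.sum() <= 0:
        w = np.ones(len(states))
    return w / w.sum()


def state_prior(ploidy: int, model: str = "noDR", q: float = 0.0) -> np.ndarray:
    """Locus-wise prior over joint ancestry states (duplicated-index states
    carry q-scaled mass under the DR model)."""
    allow_dr = _check_model(model)
    p = _parent_prior(ploidy, allow_dr, q)
    return np.kron(p, p)


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------


def _state_origin_index(states: list[AncestryState], ploidy: int) -> np.ndarray:
    """(S, ploidy) 0-based global homolog column index per inherited copy."""
    return np.array([[h - 1 for h in s.origins] for s in states], dtype=np.int64)


def expected_dosages(states: list[AncestryState], pmap: PhasedMap) -> np.ndarray:
    """(M, S) dosage implied by each state at each marker."""
    idx = _state_origin_index(states, pmap.ploidy)
    return pmap.alleles[:, idx].sum(axis=2)


def emission_prob(
    state: AncestryState,
    marker_alleles: np.ndarray,
    observed_dosage: float,
    eps: float,
    ploidy: int | None = None,
) -> float:
    """P(observed dosage | state) for a single marker.

    ``marker_alleles`` is the length-2*ploidy phased allele row.  A missing
    observation (NaN/None) is uninformative and returns 1.
    """
    if observed_dosage is None or (
        isinstance(observed_dosage, float) and np.isnan(observed_dosage)
    ):
        return 1.0
    alleles = np.asarray(marker_alleles)
    if ploidy is None:
        ploidy = alleles.shape[-1] // 2
    expected = int(sum(alleles[h - 1] for h in state.origins))
    if int(observed_dosage) == expected:
        return 1.0 - eps
    return eps / ploidy


def _emission_matrix(
    obs_row: np.ndarray, expected_row: np.ndarray, eps: float, ploidy: int
) -> np.ndarray:
    """(N, S) emission probabilities for one marker."""
    n = obs_row.shape[0]
    e = np.ones((n, expected_row.shape[0]))
    seen = ~np.isnan(obs_row)
    match = obs_row[seen, None] == expected_row[None, :]
    e[seen] = np.where(match, 1.0 - eps, eps / ploidy)
    return e


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IBDProbabilities:
    """Posterior ancestry probabilities, individuals x loci x states."""

    probs: np.ndarray  # (N, L, S)
    positions: np.ndarray  # (L,)
    states: list[AncestryState]
    ploidy: int
    model: str
    q: float
    eps: float
    on_grid: bool = False
    extrapolated: np.ndarray | None = None  # (L,) bool, grid outside marker span

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    def state_index(self) -> dict[AncestryState, int]:
        return {s: i for i, s in enumerate(self.states)}


@dataclasses.dataclass
class HaplotypeProbs:
    """Per-homolog expected copy counts pi, individuals x loci x homologs.

    Under noDR each entry is a probability in [0, 1]; under DR entries can
    reach 2.  Per parent, the homolog sum equals ploidy/2 at every locus.
    """

    pi: np.ndarray  # (N, L, 2*ploidy)
    positions: np.ndarray
    ploidy: int
    model: str


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------


def ibd_posterior(
    dosages: DosageMatrix | np.ndarray,
    pmap: PhasedMap,
    model: str = "noDR",
    q: float = 0.0,
    eps: float = 0.001,
) -> IBDProbabilities:
    """Forward-backward posterior ancestry probabilities at marker positions.

    Individuals are independent; rows are normalized.  Individuals with no
    observed marker receive the uniform posterior (with a warning).
    """
    allow_dr = _check_model(model)
    values = dosages.values if isinstance(dosages, DosageMatrix) else np.asarray(
        dosages, dtype=float
    )
    m, n = values.shape
    if m != pmap.n_markers:
        raise ValueError("dosage matrix and map have different marker counts")
    states = enumerate_ibd_states(pmap.ploidy, allow_dr)
    s = len(states)
    expected = expected_dosages(states, pmap)  # (M, S)
    prior = state_prior(pmap.ploidy, model, q)

    trans = [
        transition_matrix(pmap.ploidy, float(d), model, q)
        for d in np.diff(pmap.positions)
    ]
    emis = [
        _emission_matrix(values[mk], expected[mk], eps, pmap.ploidy)
        for mk in range(m)
    ]

    # scaled forward pass, vectorized over individuals
    alpha = np.empty((m, n, s))
    a = prior[None, :] * emis[0]
    a = _normalize_rows(a, prior)
    alpha[0] = a
    for mk in range(1, m):
        a = (a @ trans[mk - 1]) * emis[mk]
        a = _normalize_rows(a, prior)
        alpha[mk] = a

    beta = np.ones((n, s))
    post = np.empty((m, n, s))
    post[m - 1] = alpha[m - 1]
    for mk in range(m - 2, -1, -1):
        beta = (beta * emis[mk + 1]) @ trans[mk].T
        beta /= np.maximum(beta.sum(axis=1, keepdims=True), 1e-300)
        p = alpha[mk] * beta
        post[mk] = _normalize_rows(p, prior)

    probs = np.transpose(post, (1, 0, 2))  # (N, M, S)

    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} individual(s) have no observed markers; "
            "their posterior is uniform",
            stacklevel=2,
        )
        probs[all_missing] = 1.0 / s

    return IBDProbabilities(
        probs=probs,
        positions=pmap.positions.copy(),
        states=states,
        ploidy=pmap.ploidy,
        model=model,
        q=q,
        eps=eps,
        on_grid=False,
    )


def _normalize_rows(a: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    tot = a.sum(axis=1, keepdims=True)
    dead = tot[:, 0] <= 0
    if dead.any():
        a = a.copy()
        a[dead] = fallback
        tot = a.sum(axis=1, keepdims=True)
    return a / tot


def haplotype_probs(ibd: IBDProbabilities) -> HaplotypeProbs:
    """Expected per-homolog copy counts pi from a state posterior."""
    counts = np.zeros((len(ibd.states), 2 * ibd.ploidy))
    for i, st in enumerate(ibd.states):
        for h in st.origins:
            counts[i, h - 1] += 1.0
    pi = np.tensordot(ibd.probs, counts, axes=([2], [0]))  # (N, L, 2p)
    return HaplotypeProbs(
        pi=pi, positions=ibd.positions.copy(), ploidy=ibd.ploidy, model=ibd.model
    )


# ---------------------------------------------------------------------------
# Interpolation to a grid
# ---------------------------------------------------------------------------


def _dedup_positions(positions: np.ndarray, probs: np.ndarray):
    """Average posteriors over coincident marker positions (Pchip needs a
    strictly increasing abscissa)."""
    if np.all(np.diff(positions) > 0):
        return positions, probs
    uniq, inv = np.unique(positions, return_inverse=True)
    out = np.zeros(probs.shape[:1] + (len(uniq),) + probs.shape[2:])
    cnt = np.bincount(inv, minlength=len(uniq)).astype(float)
    for k in range(len(positions)):
        out[:, inv[k]] += probs[:, k]
    out /= cnt[None, :, None]
    return uniq, out


def _select_lambda(x: np.ndarray, cols: np.ndarray) -> float:
    """Shared smoothing penalty by generalized cross-validation.

    One lambda is chosen for all individual x state curves (the smoother
    trace depends only on x, so tr(S) comes from pushing the identity
    through the fixed-lambda fit; the residual term is averaged over a
    spread of representative columns).
    """
    n = len(x)
    eye = np.eye(n)
    best_lam, best_score = 1.0, np.inf
    for lam in np.logspace(-4.0, 4.0, 17):
        smoother = make_smoothing_spline(x, eye, lam=lam)(x)
        edf = float(np.trace(smoother))
        if edf / n > 0.995:
            continue
        fitted = smoother @ cols
        rss = ((cols - fitted) ** 2).sum(axis=0).mean()
        score = (rss / n) / (1.0 - edf / n) ** 2
        if score < best_score:
            best_lam, best_score = lam, score
    return best_lam


def spline_to_grid(
    ibd: IBDProbabilities,
    step: float = 1.0,
    grid: np.ndarray | None = None,
    lam: float | None = None,
) -> IBDProbabilities:
    """Re-express state posteriors on a regular grid (default 1 cM).

    Per-state cubic smoothing splines are fitted across marker positions
    and evaluated at the grid, then clipped to [0, 1] and renormalized so
    each row sums to 1.  The smoothing penalty is shared across curves and
    chosen by generalized cross-validation unless ``lam`` is given; exactly
    linear profiles are reproduced exactly.  With fewer than five markers a
    shape-preserving interpolant is used instead (too few points to
    cross-validate a penalty).  Grid points outside the marker span are
    held at the nearest marker value and flagged in ``extrapolated``.
    """
    if len(ibd.positions) < 2:
        raise ValueError("grid interpolation needs at least 2 marker positions")
    if grid is None:
        grid = np.arange(0.0, np.floor(ibd.positions.max()) + 0.5 * step, step)
    grid = np.asarray(grid, dtype=float)
    x, probs = _dedup_positions(ibd.positions, ibd.probs)
    lo, hi = x[0], x[-1]
    extrapolated = (grid < lo) | (grid > hi)
    xq = np.clip(grid, lo, hi)
    if len(x) >= 5:
        if lam is None:
            flat = probs.reshape(probs.shape[0], probs.shape[1], -1)
            flat = np.moveaxis(flat, 1, 0).reshape(len(x), -1)
            take = np.linspace(0, flat.shape[1] - 1, min(64, flat.shape[1]))
            lam = _select_lambda(x, flat[:, take.astype(int)])
        spline = make_smoothing_spline(x, probs, axis=1, lam=lam)
        vals = spline(xq)
    elif len(x) >= 2:
        interp = PchipInterpolator(x, probs, axis=1, extrapolate=False)
        vals = interp(xq)
    else:  # single unique position: constant
        vals = np.repeat(probs, len(xq), axis=1)
    vals = np.clip(vals, 0.0, 1.0)
    tot = vals.sum(axis=2, keepdims=True)
    bad = tot[..., 0] <= 0
    if bad.any():
        vals[bad] = 1.0
        tot = vals.sum(axis=2, keepdims=True)
    vals = vals / tot
    return IBDProbabilities(
        probs=vals,
        positions=grid,
        states=ibd.states,
        ploidy=ibd.ploidy,
        model=ibd.model,
        q=ibd.q,
        eps=ibd.eps,
        on_grid=True,
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_ibd_tsv(ibd: IBDProbabilities, path, states_path=None) -> None:
    """Long-format TSV ``individual position_cM state_id probability`` plus an
    optional state-definition TSV."""
    n, l, s = ibd.probs.shape
    ind = np.repeat(np.arange(1, n + 1), l * s)
    pos = np.tile(np.repeat(ibd.positions, s), n)
    sid = np.tile(np.arange(s), n * l)
    pd.DataFrame(
        {
            "individual": ind,
            "position_cM": pos,
            "state_id": sid,
            "probability": ibd.probs.reshape(-1),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
    if states_path is not None:
        pd.DataFrame(
            {
                "state_id": np.arange(s),
                "maternal": [",".join(map(str, st.maternal)) for st in ibd.states],
                "paternal": [",".join(map(str, st.paternal)) for st in ibd.states],
                "dr": [st.dr for st in ibd.states],
            }
        ).to_csv(states_path, sep="\t", index=False)
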