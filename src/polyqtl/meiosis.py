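"""Autopolyploid meiosis and F1 population simulation.

With probability ``1 - q`` the homologs of a parent pair as random bivalents;
with probability ``q`` they form a single ring multivalent.  Crossovers are
placed by a Poisson process with no interference (Haldane), so the expected
number of crossovers seen by an inherited chromatid is ``length / 100`` per
bivalent-equivalent pairing.

The multivalent model pairs homologs arm-by-arm around the centromere in a
ring (partner switch at the centromere).  Double reduction arises when a
crossover moves a segment between two homologs whose centromeres then
co-segregate to the same pole: the frequency of double reduction is exactly
zero at the centromere and rises with distance from it, matching the
qualitative behavior expected of quadrivalent meiosis.  Exact equivalence
with any particular external simulator is not claimed.

Truth records (chromatid mosaics with homolog-of-origin) are kept for every
gamete, so exact ancestry at any position is recoverable for validation.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right

import numpy as np
import pandas as pd

from polyqtl.maps import PhasedMap

__all__ = [
    "Chromatid",
    "Gamete",
    "Population",
    "DosageMatrix",
    "simulate_gamete",
    "simulate_population",
    "dr_rate",
    "genotype_population",
    "true_ibd",
    "true_qtl_dosage",
    "write_truth_tsv",
    "write_dosage_tsv",
    "read_dosage_tsv",
]


@dataclasses.dataclass
class Chromatid:
    """A single inherited chromatid as a mosaic of parental-homolog segments.

    ``breaks`` are the interior breakpoints (sorted, in cM); ``origins`` has
    one more entry than ``breaks`` and gives the 1-based parental homolog of
    origin on each segment.
    """

    breaks: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos: float) -> int:
        return int(self.origins[bisect_right(self.breaks.tolist(), pos)])

    def origins_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks, positions, side="right")
        return self.origins[idx]

    def segments(self, length: float) -> list[tuple[float, float, int]]:
        edges = np.concatenate([[0.0], self.breaks, [length]])
        return [
            (float(edges[i]), float(edges[i + 1]), int(o))
            for i, o in enumerate(self.origins)
        ]


@dataclasses.dataclass
class Gamete:
    """ploidy/2 chromatids, each tiling [0, length]."""

    chromatids: list[Chromatid]
    length: float

    def origins_at(self, pos: float) -> tuple[int, ...]:
        return tuple(sorted(c.origin_at(pos) for c in self.chromatids))

    def has_double_reduction(self, pos: float) -> bool:
        o = self.origins_at(pos)
        return len(set(o)) < len(o)

    def n_crossovers(self) -> int:
        return int(sum(len(c.breaks) for c in self.chromatids))


@dataclasses.dataclass
class Population:
    """An F1 population: per offspring one maternal and one paternal gamete."""

    offspring: list[tuple[Gamete, Gamete]]
    pmap: PhasedMap
    q: float
    seed: object = None

    @property
    def size(self) -> int:
        return len(self.offspring)


# ---------------------------------------------------------------------------
# Gamete simulation
# ---------------------------------------------------------------------------


def _bivalent_chromatid(
    h1: int, h2: int, length: float, rng: np.random.Generator
) -> Chromatid:
    # inherited-chromatid origin switches between the two paired homologs at
    # Poisson rate 1 per Morgan => Haldane recombination fractions
    n = rng.poisson(length / 100.0)
    breaks = np.sort(rng.uniform(0.0, length, size=n))
    start = int(rng.integers(2))
    pair = (h1, h2)
    origins = np.array([pair[(start + i) % 2] for i in range(n + 1)], dtype=np.int64)
    return Chromatid(breaks=breaks, origins=origins)


def _bivalent_gamete(ploidy: int, length: float, rng: np.random.Generator) -> Gamete:
    order = rng.permutation(ploidy) + 1
    chromatids = [
        _bivalent_chromatid(int(order[2 * i]), int(order[2 * i + 1]), length, rng)
        for i in range(ploidy // 2)
    ]
    return Gamete(chromatids=chromatids, length=length)


def _split(ch: tuple[list, list], x: float) -> tuple[tuple, tuple]:
    """Split a (breaks, origins) mosaic at x into [0,x) and [x, L] parts."""
    breaks, origins = ch
    i = bisect_right(breaks, x)
    left = (breaks[:i], origins[: i + 1])
    right = (breaks[i:], origins[i:])
    return left, right


def _join(left: tuple, right: tuple, x: float) -> tuple[list, list]:
    lb, lo = left
    rb, ro = right
    if lo and ro and lo[-1] == ro[0]:
        return (list(lb) + list(rb), list(lo) + list(ro[1:]))
    return (list(lb) + [x] + list(rb), list(lo) + list(ro))


def _swap_distal(chroms: list, i: int, j: int, x: float, left_arm: bool) -> None:
    """Exchange the arm-distal portions of chromatids i and j at position x.

    For the left arm the distal portion is [0, x); for the right arm it is
    [x, L].  Chromatids are (breaks, origins) list pairs, mutated in place.
    """
    li, ri = _split(chroms[i], x)
    lj, rj = _split(chroms[j], x)
    if left_arm:
        chroms[i] = _join(lj, ri, x)
        chroms[j] = _join(li, rj, x)
    else:
        chroms[i] = _join(li, rj, x)
        chroms[j] = _join(lj, ri, x)


def _multivalent_gamete(
    ploidy: int, length: float, centromere: float, rng: np.random.Generator
) -> Gamete:
    """Ring multivalent of all homologs; partner switch at the centromere."""
    ring = (rng.permutation(ploidy) + 1).tolist()
    # two sister chromatids per homolog, initially unrecombined
    chroms: list = [([], [h]) for h in ring for _ in range(2)]
    slot = {h: 2 * k for k, h in enumerate(ring)}  # first chromatid index

    arms = [
        (0.0, centromere, True),  # left arm, distal toward 0
        (centromere, length, False),  # right arm, distal toward length
    ]
    for lo, hi, left_arm in arms:
        arm_len = hi - lo
        if arm_len <= 0:
            continue
        # pairing partners alternate around the ring between the two arms
        if left_arm:
            pairs = [(ring[2 * k], ring[2 * k + 1]) for k in range(ploidy // 2)]
        else:
            pairs = [
                (ring[(2 * k + 1) % ploidy], ring[(2 * k + 2) % ploidy])
                for k in range(ploidy // 2)
            ]
        for h1, h2 in pairs:
            n = rng.poisson(2.0 * arm_len / 100.0)  # tetrad crossover rate
            xs = np.sort(rng.uniform(lo, hi, size=n))
            if left_arm:
                xs = xs[::-1]  # apply from centromere outward
            for x in xs:
                i = slot[h1] + int(rng.integers(2))
                j = slot[h2] + int(rng.integers(2))
                _swap_distal(chroms, i, j, float(x), left_arm)

    # anaphase I: random 2-2 (or 3-3) disjunction of centromeres, then a
    # random chromatid from each co-segregating centromere
    pole = rng.choice(ploidy, size=ploidy // 2, replace=False)
    chromatids = []
    for k in pole:
        h = ring[k]
        br, orig = chroms[slot[h] + int(rng.integers(2))]
        chromatids.append(
            Chromatid(
                breaks=np.asarray(br, dtype=float),
                origins=np.asarray(orig, dtype=np.int64),
            )
        )
    return Gamete(chromatids=chromatids, length=length)


def simulate_gamete(
    ploidy: int,
    length_cm: float,
    q: float,
    rng: np.random.Generator,
    centromere: float | None = None,
) -> Gamete:
    """Simulate one gamete from a parent of the given ploidy.

    With probability ``1 - q`` all homologs pair as random bivalents (no
    double reduction possible); with probability ``q`` a ring multivalent
    forms, permitting double reduction away from the centromere.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if centromere is None:
        centromere = length_cm / 2.0
    if rng.random() < q:
        return _multivalent_gamete(ploidy, length_cm, centromere, rng)
    return _bivalent_gamete(ploidy, length_cm, rng)


def simulate_population(pmap: PhasedMap, n: int, q: float, seed=None) -> Population:
    """Simulate ``n`` independent F1 offspring (one chromosome each)."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    offspring = []
    for _ in range(n):
        mat = simulate_gamete(pmap.ploidy, pmap.length, q, rng, pmap.centromere)
        pat = simulate_gamete(pmap.ploidy, pmap.length, q, rng, pmap.centromere)
        offspring.append((mat, pat))
    return Population(offspring=offspring, pmap=pmap, q=q, seed=seed)


# ---------------------------------------------------------------------------
# Truth extraction
# ---------------------------------------------------------------------------


def dr_rate(population: Population, positions) -> np.ndarray:
    """Per-position fraction of gametes carrying a duplicated homolog origin."""
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    _check_positions(positions, population.pmap.length)
    counts = np.zeros(len(positions))
    n_gam = 0
    for mat, pat in population.offspring:
        for g in (mat, pat):
            n_gam += 1
            for k, pos in enumerate(positions):
                if g.has_double_reduction(float(pos)):
                    counts[k] += 1
    return counts / n_gam


def _check_positions(positions: np.ndarray, length: float) -> None:
    if positions.min() < 0 or positions.max() > length:
        raise ValueError("positions must lie within [0, map length]")


def true_ibd(population: Population, grid_positions) -> tuple[np.ndarray, np.ndarray]:
    """Exact ancestry per individual and position.

    Returns ``(maternal, paternal)`` integer arrays of shape
    ``(N, P, ploidy/2)``; each row holds the sorted multiset of inherited
    homolog origins (1..ploidy, local to each parent).
    """
    positions = np.atleast_1d(np.asarray(grid_positions, dtype=float))
    _check_positions(positions, population.pmap.length)
    half = population.pmap.ploidy // 2
    n = population.size
    mat = np.zeros((n, len(positions), half), dtype=np.int64)
    pat = np.zeros_like(mat)
    for i, (gm, gp) in enumerate(population.offspring):
        for out, g in ((mat, gm), (pat, gp)):
            per_chrom = np.stack(
                [c.origins_at(positions) for c in g.chromatids], axis=1
            )
            out[i] = np.sort(per_chrom, axis=1)
    return mat, pat


def true_qtl_dosage(
    population: Population, position: float, q_homologs
) -> np.ndarray:
    """Per-individual copy count of the homologs in ``q_homologs`` (global
    1..2*ploidy numbering) at ``position``, counting multiplicity."""
    ploidy = population.pmap.ploidy
    q_set = set(int(h) for h in q_homologs)
    d = np.zeros(population.size, dtype=np.int64)
    for i, (mat, pat) in enumerate(population.offspring):
        # count maternal (global index = origin) and paternal (origin+ploidy)
        count = 0
        for ch in mat.chromatids:
            if ch.origin_at(position) in q_set:
                count += 1
        for ch in pat.chromatids:
            if ch.origin_at(position) + ploidy in q_set:
                count += 1
        d[i] = count
    return d


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DosageMatrix:
    """Observed SNP dosages, markers x individuals; NaN marks missing."""

    values: np.ndarray  # float (M, N), entries 0..ploidy or NaN
    ploidy: int
    eps: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = np.isnan(self.values) | (
            (self.values >= 0) & (self.values <= self.ploidy)
        )
        if not ok.all():
            raise ValueError("dosages must be in 0..ploidy or NaN")


def genotype_population(
    population: Population,
    pmap: PhasedMap | None = None,
    eps: float = 0.0,
    missing_rate: float = 0.0,
    seed=None,
) -> DosageMatrix:
    """Score marker dosages for every offspring.

    The true dosage is the sum of parental marker alleles over the inherited
    chromatid origins.  With probability ``eps`` the observed dosage is
    replaced by a uniform draw from the other ploidy classes; with
    probability ``missing_rate`` the entry is missing (NaN).
    """
    if pmap is None:
        pmap = population.pmap
    if not (0.0 <= eps < 1.0 and 0.0 <= missing_rate < 1.0):
        raise ValueError("eps and missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ploidy = pmap.ploidy
    m, n = pmap.n_markers, population.size
    truth = np.zeros((m, n), dtype=np.int64)
    for i, (mat, pat) in enumerate(population.offspring):
        dose = np.zeros(m, dtype=np.int64)
        for ch in mat.chromatids:
            idx = ch.origins_at(pmap.positions) - 1
            dose += pmap.alleles[np.arange(m), idx]
        for ch in pat.chromatids:
            idx = ploidy + ch.origins_at(pmap.positions) - 1
            dose += pmap.alleles[np.arange(m), idx]
        truth[:, i] = dose

    obs = truth.astype(float)
    if eps > 0:
        err = rng.random((m, n)) < eps
        shift = rng.integers(0, ploidy, size=(m, n))
        wrong = shift + (shift >= truth)  # uniform over the other classes
        obs[err] = wrong[err]
    if missing_rate > 0:
        obs[rng.random((m, n)) < missing_rate] = np.nan
    return DosageMatrix(values=obs, ploidy=ploidy, eps=eps, missing_rate=missing_rate)


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------


def write_truth_tsv(population: Population, path) -> None:
    """Truth segments as TSV:
    ``individual parent chromatid start_cM end_cM homolog``."""
    rows = []
    for i, (mat, pat) in enumerate(population.offspring):
        for parent, g in (("maternal", mat), ("paternal", pat)):
            for c, ch in enumerate(g.chromatids):
                for start, end, hom in ch.segments(g.length):
                    rows.append((i + 1, parent, c + 1, start, end, hom))
    pd.DataFrame(
        rows,
        columns=["individual", "parent", "chromatid", "start_cM", "end_cM", "homolog"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_dosage_tsv(dosages: DosageMatrix, marker_names, path) -> None:
    df = pd.DataFrame(
        dosages.values,
        index=pd.Index(marker_names, name="marker"),
        columns=[f"ind{i + 1}" for i in range(dosages.values.shape[1])],
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_dosage_tsv(path, ploidy: int) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return DosageMatrix(values=df.to_numpy(dtype=float), ploidy=ploidy)
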