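"""Phased parental linkage maps and marker segregation-type algebra.

A marker in an outcrossing autopolyploid F1 cross is characterized by its
maternal x paternal dosage pair (e.g. 1x0 = simplex x nulliplex).  Dosage
pairs fall into canonical equivalence classes under homozygous-parent
normalization and joint allele complementation; only canonical classes need
to be considered when simulating or analysing a cross.

This module also provides generators for synthetic phased maps with
controllable marker coverage (even vs. clustered/uneven), used throughout
the simulation studies in place of real phased linkage maps.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhasedMap",
    "SegregationType",
    "CoverageProfile",
    "UniformProfile",
    "ClusteredProfile",
    "convert_marker_type",
    "enumerate_segregation_types",
    "generate_phased_map",
    "generate_map_from_founders",
    "even_coverage_map",
    "uneven_coverage_map",
    "read_map_tsv",
    "write_map_tsv",
]


# ---------------------------------------------------------------------------
# Segregation-type algebra
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, order=True)
class SegregationType:
    """A maternal x paternal dosage class, e.g. SxN = 1x0."""

    d1: int
    d2: int
    canonical: bool = True

    def __str__(self) -> str:  # "1x0" style
        return f"{self.d1}x{self.d2}"


def _normalize(d: int, ploidy: int) -> int:
    # homozygous parents (dosage 0 or ploidy) carry no linkage information:
    # recode to 0
    return 0 if d in (0, ploidy) else d


def convert_marker_type(d1: int, d2: int, ploidy: int) -> tuple[int, int]:
    """Canonical representative of a dosage pair.

    Applies, to a fixed point, (i) homozygous-parent normalization
    (d -> 0 when d in {0, ploidy}) and (ii) the joint allele complement
    (d1, d2) -> (ploidy - d1, ploidy - d2) followed by (i), returning the
    lexicographically smallest reachable pair.  Idempotent.
    """
    if not (0 <= d1 <= ploidy and 0 <= d2 <= ploidy):
        raise ValueError(
            f"dosages ({d1},{d2}) out of range for ploidy {ploidy}"
        )
    seen: set[tuple[int, int]] = set()
    frontier = [(d1, d2)]
    while frontier:
        a, b = frontier.pop()
        a, b = _normalize(a, ploidy), _normalize(b, ploidy)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        frontier.append((ploidy - a, ploidy - b))
    return min(seen)


def enumerate_segregation_types(ploidy: int) -> list[SegregationType]:
    """All distinct canonical classes of *segregating* dosage pairs.

    9 classes at ploidy 4 and 19 at ploidy 6.
    """
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    canon = set()
    for d1 in range(ploidy + 1):
        for d2 in range(ploidy + 1):
            c = convert_marker_type(d1, d2, ploidy)
            if c != (0, 0):  # (0,0) = both parents homozygous, non-segregating
                canon.add(c)
    return [SegregationType(a, b) for a, b in sorted(canon)]


def _parse_seg_type(key, ploidy: int) -> tuple[int, int]:
    """Accept '1x0' strings, SegregationType, or (d1, d2) tuples."""
    if isinstance(key, SegregationType):
        d1, d2 = key.d1, key.d2
    elif isinstance(key, str):
        a, _, b = key.lower().partition("x")
        d1, d2 = int(a), int(b)
    else:
        d1, d2 = int(key[0]), int(key[1])
    if convert_marker_type(d1, d2, ploidy) != (d1, d2):
        raise ValueError(
            f"segregation type {d1}x{d2} is not canonical at ploidy {ploidy}; "
            f"convert it first (canonical form: "
            f"{'x'.join(map(str, convert_marker_type(d1, d2, ploidy)))})"
        )
    return d1, d2


# ---------------------------------------------------------------------------
# PhasedMap
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PhasedMap:
    """A phased parental linkage map for one chromosome.

    Attributes
    ----------
    chromosome : str
        Chromosome identifier.
    length : float
        Chromosome length in centiMorgans.
    names : list of str
        Marker names, in map order.
    positions : ndarray, shape (M,)
        Marker positions in cM, non-decreasing, within [0, length].
    alleles : ndarray of 0/1, shape (M, 2 * ploidy)
        Per-homolog phased alleles; columns 1..ploidy are maternal homologs,
        ploidy+1..2*ploidy paternal (1-based homolog numbering).
    ploidy : int
        Even ploidy level (4 = autotetraploid).
    centromere : float
        Centromere position in cM (defaults to the chromosome midpoint);
        used by the meiosis simulator's multivalent model.
    """

    chromosome: str
    length: float
    names: list[str]
    positions: np.ndarray
    alleles: np.ndarray
    ploidy: int
    centromere: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2")
        if self.n_markers == 0:
            raise ValueError("a phased map must contain at least one marker")
        if self.alleles.shape != (self.n_markers, 2 * self.ploidy):
            raise ValueError("alleles must have shape (n_markers, 2*ploidy)")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("marker positions must be non-decreasing")
        if self.positions[0] < 0 or self.positions[-1] > self.length + 1e-9:
            raise ValueError("marker positions must lie within [0, length]")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele entries must be 0 or 1")
        d1 = self.maternal_dosage
        d2 = self.paternal_dosage
        seg = ((d1 > 0) & (d1 < self.ploidy)) | ((d2 > 0) & (d2 < self.ploidy))
        if not seg.all():
            bad = [self.names[i] for i in np.flatnonzero(~seg)[:5]]
            raise ValueError(f"non-segregating markers in map: {bad}")
        if self.centromere is None:
            self.centromere = self.length / 2.0

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def maternal_dosage(self) -> np.ndarray:
        return self.alleles[:, : self.ploidy].sum(axis=1)

    @property
    def paternal_dosage(self) -> np.ndarray:
        return self.alleles[:, self.ploidy :].sum(axis=1)

    def segregation_types(self) -> list[tuple[int, int]]:
        """Canonical segregation type of each marker."""
        return [
            convert_marker_type(int(a), int(b), self.ploidy)
            for a, b in zip(self.maternal_dosage, self.paternal_dosage)
        ]


# ---------------------------------------------------------------------------
# Coverage profiles
# ---------------------------------------------------------------------------


class CoverageProfile:
    """Marker-density profile along a chromosome.

    Subclasses supply a cdf (for goodness-of-fit checks) and a sampler.
    """

    def cdf(self, x: np.ndarray, length: float) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n: int, length: float, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class UniformProfile(CoverageProfile):
    """Even coverage: positions i.i.d. uniform on [0, length]."""

    def cdf(self, x, length):
        return np.clip(np.asarray(x, dtype=float) / length, 0.0, 1.0)

    def sample(self, n, length, rng):
        return np.sort(rng.uniform(0.0, length, size=n))


class ClusteredProfile(CoverageProfile):
    """Uneven coverage: mixture of truncated-normal clusters over a uniform
    background, giving marker-dense and marker-poor regions.

    Parameters are fractions of the chromosome length, so one profile can be
    reused across maps of different lengths.
    """

    def __init__(
        self,
        centers: Sequence[float] = (0.15, 0.5, 0.85),
        widths: Sequence[float] | float = 0.05,
        weights: Sequence[float] | None = None,
        background: float = 0.3,
    ) -> None:
        self.centers = np.asarray(centers, dtype=float)
        if np.isscalar(widths):
            widths = np.full(len(self.centers), float(widths))
        self.widths = np.asarray(widths, dtype=float)
        if weights is None:
            weights = np.ones(len(self.centers))
        weights = np.asarray(weights, dtype=float)
        if not 0.0 <= background <= 1.0:
            raise ValueError("background fraction must be in [0, 1]")
        self.background = float(background)
        self.cluster_w = (1.0 - background) * weights / weights.sum()

    def _components(self, length):
        for c, w in zip(self.centers * length, self.widths * length):
            a, b = (0.0 - c) / w, (length - c) / w
            yield stats.truncnorm(a, b, loc=c, scale=w)

    def cdf(self, x, length):
        x = np.asarray(x, dtype=float)
        out = self.background * np.clip(x / length, 0.0, 1.0)
        for w, comp in zip(self.cluster_w, self._components(length)):
            out = out + w * comp.cdf(x)
        return out

    def sample(self, n, length, rng):
        probs = np.concatenate([[self.background], self.cluster_w])
        which = rng.choice(len(probs), size=n, p=probs)
        pos = np.empty(n)
        bg = which == 0
        pos[bg] = rng.uniform(0.0, length, size=bg.sum())
        comps = list(self._components(length))
        for k, comp in enumerate(comps, start=1):
            sel = which == k
            pos[sel] = comp.rvs(size=sel.sum(), random_state=rng)
        return np.sort(pos)


def _resolve_profile(profile) -> CoverageProfile:
    if isinstance(profile, CoverageProfile):
        return profile
    if profile == "uniform":
        return UniformProfile()
    if profile == "clustered":
        return ClusteredProfile()
    raise ValueError(f"unknown coverage profile: {profile!r}")


# ---------------------------------------------------------------------------
# Map generators
# ---------------------------------------------------------------------------


def _weighted_subset(
    rng: np.random.Generator, k: int, n: int, weights: np.ndarray | None
) -> np.ndarray:
    if weights is None:
        return rng.choice(n, size=k, replace=False)
    w = np.asarray(weights, dtype=float)
    return rng.choice(n, size=k, replace=False, p=w / w.sum())


def generate_phased_map(
    ploidy: int,
    n_markers: int,
    length_cm: float,
    coverage_profile="uniform",
    segregation_mix: Mapping | None = None,
    seed=None,
    chromosome: str = "chr1",
    centromere: float | None = None,
    maternal_homolog_weights: Sequence[float] | None = None,
    paternal_homolog_weights: Sequence[float] | None = None,
) -> PhasedMap:
    """Generate a random phased map.

    Parameters
    ----------
    coverage_profile : "uniform", "clustered" or CoverageProfile
        Marker-density profile along the chromosome.
    segregation_mix : mapping, optional
        Sampling weights over canonical segregation types (keys like "1x0",
        tuples or SegregationType).  Non-canonical keys are rejected.
        Defaults to equal weights over all canonical types.
    maternal_homolog_weights, paternal_homolog_weights : sequences, optional
        Relative probabilities that each homolog carries the alternative
        allele; skewing these produces homologs with poor marker coverage.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1 (empty maps are rejected)")
    rng = np.random.default_rng(seed)
    profile = _resolve_profile(coverage_profile)
    if segregation_mix is None:
        types = [(t.d1, t.d2) for t in enumerate_segregation_types(ploidy)]
        weights = np.ones(len(types))
    else:
        types = [_parse_seg_type(k, ploidy) for k in segregation_mix]
        weights = np.asarray([float(v) for v in segregation_mix.values()])
        if len(types) == 0 or weights.sum() <= 0:
            raise ValueError("segregation_mix must give positive weight")
    weights = weights / weights.sum()

    positions = profile.sample(n_markers, length_cm, rng)
    type_idx = rng.choice(len(types), size=n_markers, p=weights)
    alleles = np.zeros((n_markers, 2 * ploidy), dtype=np.int8)
    for m, ti in enumerate(type_idx):
        d1, d2 = types[ti]
        if d1:
            cols = _weighted_subset(rng, d1, ploidy, maternal_homolog_weights)
            alleles[m, cols] = 1
        if d2:
            cols = _weighted_subset(rng, d2, ploidy, paternal_homolog_weights)
            alleles[m, ploidy + cols] = 1
    names = [f"M{m + 1:04d}" for m in range(n_markers)]
    return PhasedMap(
        chromosome=chromosome,
        length=float(length_cm),
        names=names,
        positions=positions,
        alleles=alleles,
        ploidy=ploidy,
        centromere=centromere,
    )


def generate_map_from_founders(
    ploidy: int,
    n_founders: int,
    n_markers: int,
    length_cm: float,
    seed=None,
    chromosome: str = "chr1",
    allele_freq: float = 0.5,
    centromere: float | None = None,
) -> PhasedMap:
    """Generate a phased map whose parental homologs are drawn (with
    replacement) from a pool of ``n_founders`` distinct haplotypes.

    Markers that do not segregate across the sampled 2*ploidy homologs are
    dropped, so fewer founders yield fewer segregating markers on average.
    """
    if n_founders < 2:
        raise ValueError(
            "n_founders must be >= 2: a single founder haplotype cannot "
            "produce segregating markers"
        )
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.uniform(0.0, length_cm, size=n_markers))
    pool = (rng.random((n_founders, n_markers)) < allele_freq).astype(np.int8)
    draw = rng.integers(0, n_founders, size=2 * ploidy)
    alleles = pool[draw].T  # (n_markers, 2*ploidy)

    d1 = alleles[:, :ploidy].sum(axis=1)
    d2 = alleles[:, ploidy:].sum(axis=1)
    seg = ((d1 > 0) & (d1 < ploidy)) | ((d2 > 0) & (d2 < ploidy))
    if not seg.any():
        raise ValueError(
            "all markers are monomorphic/non-segregating across the sampled "
            "homologs; use a larger founder pool or more markers"
        )
    names = [f"M{m + 1:04d}" for m in np.flatnonzero(seg)]
    return PhasedMap(
        chromosome=chromosome,
        length=float(length_cm),
        names=names,
        positions=positions[seg],
        alleles=alleles[seg],
        ploidy=ploidy,
        centromere=centromere,
    )


def even_coverage_map(
    ploidy: int = 4,
    n_markers: int = 100,
    length_cm: float = 100.0,
    seed=None,
) -> PhasedMap:
    """Evenly covered map with all canonical segregation types (a stand-in
    for a chromosome with dense, homogeneous marker coverage)."""
    return generate_phased_map(
        ploidy, n_markers, length_cm, "uniform", None, seed, chromosome="chr12"
    )


def uneven_coverage_map(
    ploidy: int = 4,
    n_markers: int = 60,
    length_cm: float = 100.0,
    seed=None,
) -> PhasedMap:
    """Unevenly covered map: clustered marker positions and strongly skewed
    homolog tagging, so per-homolog information varies from rich to poor
    along the chromosome (a stand-in for a patchily covered chromosome)."""
    skew = [8.0, 3.0, 1.0, 0.25]
    weights = (skew + [1.0] * ploidy)[:ploidy]
    return generate_phased_map(
        ploidy,
        n_markers,
        length_cm,
        ClusteredProfile(centers=(0.12, 0.5, 0.85), widths=0.05, background=0.25),
        None,
        seed,
        chromosome="chr1",
        maternal_homolog_weights=weights,
        paternal_homolog_weights=weights[::-1],
    )


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------


def write_map_tsv(pmap: PhasedMap, path) -> None:
    """Write a phased map as TSV: ``marker chrom position_cM h1 .. h{2p}``."""
    cols = {"marker": pmap.names, "chrom": pmap.chromosome}
    cols["position_cM"] = [f"{p:.4f}" for p in pmap.positions]
    for j in range(2 * pmap.ploidy):
        cols[f"h{j + 1}"] = pmap.alleles[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_map_tsv(
    path, length: float | None = None, centromere: float | None = None
) -> PhasedMap:
    """Read a phased map written by :func:`write_map_tsv`."""
    df = pd.read_csv(path, sep="\t")
    hcols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
    hcols = sorted(hcols, key=lambda c: int(c[1:]))
    if len(hcols) % 2:
        raise ValueError("odd number of homolog columns in map TSV")
    ploidy = len(hcols) // 2
    positions = df["position_cM"].to_numpy(dtype=float)
    if length is None:
        length = float(np.ceil(positions[-1])) if len(positions) else 0.0
    return PhasedMap(
        chromosome=str(df["chrom"].iloc[0]),
        length=float(length),
        names=df["marker"].astype(str).tolist(),
        positions=positions,
        alleles=df[hcols].to_numpy(),
        ploidy=ploidy,
        centromere=centromere,
    )
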