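"""Phenotype simulation and the factorial QTL power/precision study engine.

Phenotypes follow P_i ~ N(mu + Q * d_i, sigma_e^2) with mu = 10, Q = 1,
where d_i is the true copy count of the positive QTL alleles in individual i
(0/1 indicator for dominant QTL).  The environmental variance is
sigma_e^2 = ((1 - h2) / h2) * sigma_g^2 with sigma_g^2 the realized
genotypic variance in the population.

``run_study`` sweeps a factor grid (multivalent rate q, population size,
heritability, QTL segregation type, gene action, position, IBD model),
simulating populations, estimating IBD, scanning, and recording detection
(interpolated LOD at the true position vs. a pooled permutation threshold),
peak distance, LOD-1/LOD-2 interval coverage and per-homolog GIC categories.
Thresholds follow the pooled scheme: each simulated phenotype set is
permuted once and the (1 - alpha) quantile of the pooled chromosome-wide
maxima forms the cell threshold.
"""

from __future__ import annotations

import dataclasses
import itertools
import traceback

import numpy as np
import pandas as pd
import yaml

from polyqtl.gic import classify_qtl_gic, gic_per_homolog
from polyqtl.ibd import haplotype_probs, ibd_posterior, spline_to_grid
from polyqtl.maps import PhasedMap, even_coverage_map, uneven_coverage_map
from polyqtl.meiosis import (
    Population,
    genotype_population,
    simulate_population,
    true_qtl_dosage,
)
from polyqtl.scan import (
    build_design,
    empirical_threshold,
    interpolate_lod,
    lod_profiles,
    support_interval,
)

__all__ = [
    "TraitSet",
    "StudyConfig",
    "NonSegregatingQTLError",
    "simulate_phenotypes",
    "draw_qtl_homologs",
    "run_study",
    "summarize_records",
    "gic_power_table",
    "load_study_config",
]


class NonSegregatingQTLError(ValueError):
    """The QTL does not segregate in the realized population."""


@dataclasses.dataclass
class TraitSet:
    """Simulated phenotypes plus the QTL truth used to generate them."""

    y: np.ndarray
    d: np.ndarray  # per-individual genotypic score
    qtl_position: float
    q_homologs: tuple[int, ...]
    action: str
    h2: float
    sigma_g2: float
    sigma_e2: float
    mu: float = 10.0
    effect: float = 1.0


def simulate_phenotypes(
    population: Population,
    qtl_position: float,
    q_homologs,
    action: str,
    h2: float,
    seed=None,
    mu: float = 10.0,
    effect: float = 1.0,
    allele_effects: dict | None = None,
) -> TraitSet:
    """Draw one phenotype set for a simulated population.

    ``q_homologs`` are global homolog indices (1..2*ploidy) carrying the
    positive allele.  ``action`` is "additive" or "dominant" (dosage coded
    0/1).  ``h2 = 0`` is the pure-noise control: y ~ N(mu, 1), no QTL
    effect.  ``allele_effects`` optionally maps homolog -> effect for
    multi-allelic QTL (replacing the Q * d_i term by the summed effects of
    the inherited homologs).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if not 0.0 <= qtl_position <= population.pmap.length:
        raise ValueError("QTL position outside the map")
    rng = np.random.default_rng(seed)
    n = population.size
    if allele_effects is not None:
        g = np.zeros(n)
        for hom, eff in allele_effects.items():
            g += eff * true_qtl_dosage(population, qtl_position, (int(hom),))
        d = g.copy()
    else:
        d = true_qtl_dosage(population, qtl_position, q_homologs).astype(float)
        if action == "dominant":
            d = (d >= 1).astype(float)
        elif action != "additive":
            raise ValueError("action must be 'additive' or 'dominant'")
        g = effect * d
    if h2 == 0.0:
        y = mu + rng.normal(0.0, 1.0, size=n)
        return TraitSet(y, d, float(qtl_position), tuple(int(h) for h in q_homologs),
                        action, h2, 0.0, 1.0, mu, effect)
    sigma_g2 = float(np.var(g))
    if sigma_g2 <= 0:
        raise NonSegregatingQTLError(
            f"QTL on homolog(s) {tuple(q_homologs)} does not segregate in "
            "this population"
        )
    sigma_e2 = (1.0 - h2) / h2 * sigma_g2
    y = mu + g + rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    return TraitSet(
        y, d, float(qtl_position), tuple(int(h) for h in q_homologs),
        action, h2, sigma_g2, sigma_e2, mu, effect,
    )


def draw_qtl_homologs(seg: str, ploidy: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Random QTL phase for a segregation type ("SxN", "DxN", "SxS" or an
    explicit 'd1xd2' dosage pair)."""
    seg = seg.strip()
    key = seg.upper()
    if key == "SXN":
        parent = int(rng.integers(2))
        return (parent * ploidy + int(rng.integers(ploidy)) + 1,)
    if key == "DXN":
        parent = int(rng.integers(2))
        homs = rng.choice(ploidy, size=2, replace=False)
        return tuple(sorted(parent * ploidy + int(h) + 1 for h in homs))
    if key == "SXS":
        return (
            int(rng.integers(ploidy)) + 1,
            ploidy + int(rng.integers(ploidy)) + 1,
        )
    a, _, b = seg.lower().partition("x")
    d1, d2 = int(a), int(b)
    if not (0 <= d1 <= ploidy and 0 <= d2 <= ploidy and 0 < d1 + d2):
        raise ValueError(f"cannot draw QTL homologs for type {seg!r}")
    mat = rng.choice(ploidy, size=d1, replace=False) + 1 if d1 else np.array([], int)
    pat = rng.choice(ploidy, size=d2, replace=False) + 1 + ploidy if d2 else np.array([], int)
    return tuple(sorted(int(h) for h in np.concatenate([mat, pat])))


@dataclasses.dataclass
class StudyConfig:
    """Factor grid and replication for a power/precision study.

    Field names mirror the study interface: q (multivalent rate), Pop
    (population size), h2, QTLseg, QTLact, QTLpos, model.
    """

    q: tuple = (0.0,)
    Pop: tuple = (200,)
    h2: tuple = (0.1,)
    QTLseg: tuple = ("SxN",)
    QTLact: tuple = ("additive",)
    QTLpos: object = "random"  # "random" or a sequence of cM positions
    model: tuple = ("noDR",)
    n_pops: int = 10
    n_pheno: int = 20
    n_perm_per_set: int = 1
    alpha: float = 0.05
    eps: float = 0.001
    genotyping_eps: float = 0.0
    missing_rate: float = 0.0
    gic_thresholds: tuple = (0.9, 0.95)
    seed: int = 0
    map_kind: str = "even"  # "even" | "uneven" (ignored when a map is given)
    ploidy: int = 4
    n_markers: int = 100
    length_cm: float = 100.0

    def __post_init__(self) -> None:
        for field in ("q", "Pop", "h2", "QTLseg", "QTLact", "model"):
            v = getattr(self, field)
            if isinstance(v, (str, int, float)):
                v = (v,)
            setattr(self, field, tuple(v))
        if self.n_pops < 1 or self.n_pheno < 1 or self.n_perm_per_set < 1:
            raise ValueError("replication counts must be >= 1")
        for m in self.model:
            if m not in ("noDR", "DR"):
                raise ValueError(f"unknown model {m!r}")


def load_study_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return StudyConfig(**data)


def _build_map(config: StudyConfig, seed) -> PhasedMap:
    maker = even_coverage_map if config.map_kind == "even" else uneven_coverage_map
    return maker(config.ploidy, config.n_markers, config.length_cm, seed)


def run_study(
    config: StudyConfig, pmap: PhasedMap | None = None
) -> dict:
    """Run the factorial study; returns ``{"records", "summary", "thresholds",
    "failures", "map"}``.

    ``records`` holds one row per (population, phenotype set, model)
    replicate with truth, peak, intervals, permutation maximum, GIC values
    and detection flags.  Fully deterministic given the config seed.
    """
    master = np.random.default_rng(config.seed)
    if pmap is None:
        pmap = _build_map(config, int(master.integers(2**31)))
    ploidy = pmap.ploidy
    designs = {m: build_design(ploidy, m) for m in config.model}
    rows = []
    failures = []
    trait_cells = list(
        itertools.product(config.h2, config.QTLseg, config.QTLact)
    )
    for q_rate in config.q:
        for n_pop in config.Pop:
            for pop_i in range(config.n_pops):
                pop_seed = int(master.integers(2**31))
                geno_seed = int(master.integers(2**31))
                population = simulate_population(pmap, n_pop, q_rate, pop_seed)
                dosages = genotype_population(
                    population, pmap, config.genotyping_eps,
                    config.missing_rate, geno_seed,
                )
                grids = {}
                # noDR is always estimated: the GIC track needs it
                for m in set(config.model) | {"noDR"}:
                    ibd = ibd_posterior(
                        dosages, pmap, m,
                        q=q_rate if m == "DR" else 0.0, eps=config.eps,
                    )
                    grids[m] = spline_to_grid(ibd)
                gic_track = gic_per_homolog(haplotype_probs(grids["noDR"]))
                for h2, seg, action in trait_cells:
                    for rep in range(config.n_pheno):
                        rep_seed = int(master.integers(2**31))
                        try:
                            rows.extend(
                                _one_replicate(
                                    config, population, grids, designs,
                                    gic_track, q_rate, n_pop, pop_i, h2,
                                    seg, action, rep, rep_seed,
                                )
                            )
                        except NonSegregatingQTLError as exc:
                            failures.append(
                                dict(q=q_rate, Pop=n_pop, pop=pop_i, h2=h2,
                                     QTLseg=seg, QTLact=action, rep=rep,
                                     reason=str(exc))
                            )
                        except Exception as exc:  # record, keep running
                            failures.append(
                                dict(q=q_rate, Pop=n_pop, pop=pop_i, h2=h2,
                                     QTLseg=seg, QTLact=action, rep=rep,
                                     reason=f"{exc}\n{traceback.format_exc()}")
                            )
    records = pd.DataFrame(rows)
    thresholds = _attach_detection(records, config.alpha)
    summary = summarize_records(records) if len(records) else pd.DataFrame()
    return {
        "records": records,
        "summary": summary,
        "thresholds": thresholds,
        "failures": pd.DataFrame(failures),
        "map": pmap,
    }


def _one_replicate(
    config, population, grids, designs, gic_track,
    q_rate, n_pop, pop_i, h2, seg, action, rep, rep_seed,
):
    rng = np.random.default_rng(rep_seed)
    ploidy = population.pmap.ploidy
    if isinstance(config.QTLpos, str) and config.QTLpos == "random":
        position = float(np.round(rng.uniform(0.0, population.pmap.length), 2))
    else:
        position = float(rng.choice(np.asarray(config.QTLpos, dtype=float)))
    q_homs = draw_qtl_homologs(seg, ploidy, rng)
    traits = simulate_phenotypes(
        population, position, q_homs, action, h2,
        seed=int(rng.integers(2**31)),
    )
    perm = [
        rng.permutation(traits.y) for _ in range(config.n_perm_per_set)
    ]
    Y = np.column_stack([traits.y] + perm)
    gic_vals = [gic_track.at(position, h) for h in q_homs]
    out = []
    for m in config.model:
        grid = grids[m]
        lod = lod_profiles(Y, grid, designs[m])
        prof = lod[:, 0]
        peak_idx = int(np.argmax(prof))
        lo1, hi1 = support_interval(grid.positions, prof, 1.0)
        lo2, hi2 = support_interval(grid.positions, prof, 2.0)
        pos_lo, pos_hi = grid.positions[0], grid.positions[-1]
        lod_at_qtl = interpolate_lod(
            grid.positions, prof, min(max(position, pos_lo), pos_hi)
        )
        row = dict(
            q=q_rate, Pop=n_pop, pop=pop_i, h2=h2, QTLseg=seg,
            QTLact=action, rep=rep, model=m, position=position,
            q_homologs=",".join(map(str, q_homs)),
            sigma_g2=traits.sigma_g2,
            peak_position=float(grid.positions[peak_idx]),
            peak_lod=float(prof[peak_idx]),
            lod_at_qtl=float(lod_at_qtl),
            perm_max=float(lod[:, 1:].max(axis=0).max()),
            lod1_lo=lo1, lod1_hi=hi1, lod2_lo=lo2, lod2_hi=hi2,
        )
        for k in range(config.n_perm_per_set):
            row[f"perm_max_{k}"] = float(lod[:, 1 + k].max())
        for j, g in enumerate(gic_vals):
            row[f"gic{j + 1}"] = g
        out.append(row)
    return out


_CELL_KEYS = ["q", "Pop", "h2", "QTLseg", "QTLact", "model"]


def _attach_detection(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Pool permutation maxima per cell, set thresholds and detection flags
    (both the conservative LOD-at-true-position rule and the peak rule)."""
    if not len(records):
        return pd.DataFrame()
    perm_cols = [c for c in records.columns if c.startswith("perm_max_")]
    thr_rows = []
    records["threshold"] = np.nan
    for key, idx in records.groupby(_CELL_KEYS).groups.items():
        maxima = records.loc[idx, perm_cols].to_numpy().ravel()
        thr = empirical_threshold(maxima, alpha)
        records.loc[idx, "threshold"] = thr
        thr_rows.append(dict(zip(_CELL_KEYS, key), threshold=thr, n_perm=maxima.size))
    records["detected"] = records["lod_at_qtl"] >= records["threshold"]
    records["detected_peak"] = records["peak_lod"] >= records["threshold"]
    records["peak_distance"] = (records["peak_position"] - records["position"]).abs()
    records["lod1_covers"] = (records["position"] >= records["lod1_lo"]) & (
        records["position"] <= records["lod1_hi"]
    )
    records["lod2_covers"] = (records["position"] >= records["lod2_lo"]) & (
        records["position"] <= records["lod2_hi"]
    )
    records["lod1_width"] = records["lod1_hi"] - records["lod1_lo"]
    records["lod2_width"] = records["lod2_hi"] - records["lod2_lo"]
    return pd.DataFrame(thr_rows)


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell power/precision table."""
    rows = []
    for key, sub in records.groupby(_CELL_KEYS):
        det = sub[sub["detected"]]
        rows.append(
            dict(
                zip(_CELL_KEYS, key),
                n_reps=len(sub),
                power=sub["detected"].mean(),
                power_peak=sub["detected_peak"].mean(),
                threshold=sub["threshold"].iloc[0],
                mean_peak_distance=det["peak_distance"].mean()
                if len(det)
                else np.nan,
                lod1_cover=det["lod1_covers"].mean() if len(det) else np.nan,
                lod2_cover=det["lod2_covers"].mean() if len(det) else np.nan,
                lod1_width=det["lod1_width"].mean() if len(det) else np.nan,
                lod2_width=det["lod2_width"].mean() if len(det) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def gic_power_table(
    records: pd.DataFrame,
    thresholds=(0.9, 0.95),
    groupby=("Pop", "h2", "QTLseg", "QTLact"),
) -> pd.DataFrame:
    """Detection power of two-allele QTL by GIC category.

    Categories: LL, LH/HL (pooled) and HH, per high-GIC threshold; empty
    categories are reported as missing (NaN power, count 0).
    """
    two = records.dropna(subset=["gic2"]) if "gic2" in records else records.iloc[0:0]
    rows = []
    groupby = list(groupby)
    groups = two.groupby(groupby) if groupby else [((), two)]
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        for thr in thresholds:
            hi1 = sub["gic1"] >= thr
            hi2 = sub["gic2"] >= thr
            cats = {
                "LL": ~hi1 & ~hi2,
                "LH/HL": hi1 ^ hi2,
                "HH": hi1 & hi2,
            }
            for cat, sel in cats.items():
                cell = sub[sel]
                rows.append(
                    dict(
                        zip(groupby, key),
                        gic_threshold=thr,
                        category=cat,
                        power=cell["detected"].mean() if len(cell) else np.nan,
                        count=len(cell),
                    )
                )
    return pd.DataFrame(rows)
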