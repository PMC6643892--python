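"""Canned desk-scale study definitions used for validation.

These wrap :func:`polyqtl.power.run_study` with fixed factor grids:

* ``dr_power_gap_study`` — detection-power difference between the DR and
  noDR models for an additive simplex x nulliplex QTL at q = 0.5, N = 200,
  h2 = 0.1 on an evenly covered synthetic map (20 populations x 25
  phenotype sets by default, thresholds pooled over one permutation per
  phenotype set).
* ``lod1_miss_study`` — fraction of LOD-1 support intervals of detected
  QTL that do not contain the true simulated position under purely
  bivalent pairing (q = 0), averaged over a reduced factorial of
  population sizes, heritabilities, QTL segregation types and gene
  actions.
"""

from __future__ import annotations

import numpy as np

from polyqtl.maps import even_coverage_map
from polyqtl.power import StudyConfig, run_study

__all__ = ["dr_power_gap_study", "lod1_miss_study"]

_CELL_KEYS = ["Pop", "h2", "QTLseg", "QTLact"]


def dr_power_gap_study(seed: int = 101, n_pops: int = 20, n_pheno: int = 25) -> dict:
    """Return the DR-minus-noDR power gap (percentage points) with its
    paired Monte-Carlo standard error."""
    pmap = even_coverage_map(ploidy=4, n_markers=100, length_cm=100.0, seed=11)
    cfg = StudyConfig(
        q=(0.5,), Pop=(200,), h2=(0.1,), QTLseg=("SxN",), QTLact=("additive",),
        QTLpos=(25.0,), model=("noDR", "DR"), n_pops=n_pops, n_pheno=n_pheno,
        seed=seed,
    )
    res = run_study(cfg, pmap)
    rec = res["records"]
    wide = rec.pivot_table(
        index=["pop", "rep"], columns="model", values="detected", aggfunc="first"
    ).astype(float)
    diffs = wide["DR"] - wide["noDR"]
    gap_pp = 100.0 * diffs.mean()
    # replicates within a population share its meioses and IBD estimates, so
    # the Monte-Carlo error is cluster-robust over populations
    pop_means = diffs.groupby(level="pop").mean()
    se_pp = 100.0 * pop_means.std(ddof=1) / np.sqrt(len(pop_means))
    powers = res["summary"].set_index("model")["power"]
    return {
        "gap_pp": float(gap_pp),
        "se_pp": float(se_pp),
        "power_noDR": float(powers["noDR"]),
        "power_DR": float(powers["DR"]),
        "n": int(len(diffs)),
        "records": rec,
    }


def lod1_miss_study(seed: int = 202, n_pops: int = 10, n_pheno: int = 10) -> dict:
    """Return the cell-averaged LOD-1 interval miss rate (%) among detected
    QTL at q = 0 (random QTL positions, noDR model)."""
    pmap = even_coverage_map(ploidy=4, n_markers=100, length_cm=100.0, seed=11)
    cfg = StudyConfig(
        q=(0.0,), Pop=(200, 400), h2=(0.1, 0.2), QTLseg=("SxN", "DxN", "SxS"),
        QTLact=("additive", "dominant"), QTLpos="random", model=("noDR",),
        n_pops=n_pops, n_pheno=n_pheno, seed=seed,
    )
    res = run_study(cfg, pmap)
    rec = res["records"]
    det = rec[rec["detected"]]
    per_cell = 1.0 - det.groupby(_CELL_KEYS)["lod1_covers"].mean()
    miss_all = 1.0 - rec.groupby(_CELL_KEYS)["lod1_covers"].mean()
    return {
        "miss_pct": float(100.0 * per_cell.mean()),
        "miss_pct_all_replicates": float(100.0 * miss_all.mean()),
        "n_detected": int(len(det)),
        "n_cells": int(len(per_cell)),
        "records": rec,
    }
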