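"""Per-homolog genotypic information coefficients (GIC).

GIC_j = 1 - (4/N) * sum_n pi_n (1 - pi_n), where pi_n is the probability
that individual n inherited homolog j at the locus (bivalent-only "noDR"
haplotypic probabilities).  GIC lies in [0, 1]: it equals 1 iff every pi_n
is 0 or 1 (full information) and 0 iff every pi_n is 0.5 (no information).
The definition does not depend on the ploidy level.

A homolog-specific GIC is not well defined once an offspring can inherit
more than one copy of a homolog, so DR-model input is rejected.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from polyqtl.ibd import HaplotypeProbs

__all__ = ["GICTrack", "gic_per_homolog", "classify_qtl_gic", "write_gic_tsv"]


@dataclasses.dataclass
class GICTrack:
    """Per-homolog GIC along the chromosome (homologs x positions)."""

    values: np.ndarray  # (2*ploidy, L) in [0, 1]
    positions: np.ndarray  # (L,)
    n: int  # population size used
    ploidy: int
    model: str = "noDR"

    def at(self, position: float, homolog: int) -> float:
        """GIC of a homolog (global 1..2*ploidy) at the nearest grid point."""
        idx = int(np.argmin(np.abs(self.positions - position)))
        return float(self.values[homolog - 1, idx])


def gic_per_homolog(hap: HaplotypeProbs) -> GICTrack:
    """Compute the per-homolog GIC track from noDR haplotypic probabilities."""
    if hap.model != "noDR":
        raise ValueError(
            "GIC is only defined for the noDR model; a homolog-specific GIC "
            "is not well defined when double reduction is allowed"
        )
    pi = hap.pi
    n = pi.shape[0]
    gic = 1.0 - (4.0 / n) * (pi * (1.0 - pi)).sum(axis=0)  # (L, 2p)
    gic = np.clip(gic, 0.0, 1.0)
    return GICTrack(
        values=gic.T.copy(),
        positions=hap.positions.copy(),
        n=n,
        ploidy=hap.ploidy,
        model=hap.model,
    )


def classify_qtl_gic(
    gic_track: GICTrack,
    qtl_homologs,
    qtl_position: float,
    high_threshold: float = 0.9,
) -> str:
    """Classify the QTL-allele homologs as high (H) or low (L) information.

    ``qtl_homologs`` are the global homolog indices carrying positive-effect
    alleles; each is rated H when its GIC at the (nearest grid point to the)
    QTL position is >= ``high_threshold``, else L.  Two-allele QTL yield
    two-letter codes; LH and HL are reported distinctly but may be pooled.
    """
    if not 0.0 < high_threshold < 1.0:
        raise ValueError("high_threshold must lie in (0, 1)")
    pos = gic_track.positions
    if np.min(np.abs(pos - qtl_position)) > 1e-9:
        warnings.warn(
            f"QTL position {qtl_position} is off the GIC grid; using the "
            "nearest grid point",
            stacklevel=2,
        )
    letters = [
        "H" if gic_track.at(qtl_position, int(h)) >= high_threshold else "L"
        for h in qtl_homologs
    ]
    return "".join(letters)


def write_gic_tsv(track: GICTrack, path) -> None:
    cols = {"position_cM": track.positions}
    for j in range(2 * track.ploidy):
        cols[f"h{j + 1}"] = track.values[j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")
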