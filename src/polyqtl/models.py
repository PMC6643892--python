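"""BIC-based diagnosis of QTL configuration (phase) and mode of action.

At a QTL peak, the per-state weighted phenotype means are fitted against the
predictor implied by each candidate bi-allelic configuration: additive
(count of Q-labeled homolog copies in the state) or simplex dominant (any Q
copy present).  Candidates are ranked by
BIC = n * ln(RSS / n) + p * ln(n), with p = 2 (intercept + effect) and n the
number of fitted state means (36 noDR / 100 DR in a tetraploid).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from polyqtl.ibd import AncestryState, enumerate_ibd_states

__all__ = [
    "QTLConfiguration",
    "ModelFit",
    "class_predictor",
    "predictor_vector",
    "model_catalogue",
    "class_means",
    "bic",
    "select_model",
]

ACTIONS = ("additive", "dominant")


@dataclasses.dataclass(frozen=True)
class QTLConfiguration:
    """Bi-allelic QTL configuration: o/Q label per homolog plus gene action.

    ``labels`` has length 2*ploidy (maternal homologs first).  ``action`` is
    "additive" or "dominant" (simplex dominant: one Q copy suffices for full
    trait expression).
    """

    labels: tuple[str, ...]
    action: str

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"action must be one of {ACTIONS}")
        if any(c not in ("o", "Q") for c in self.labels):
            raise ValueError("labels must be 'o' or 'Q'")

    @property
    def ploidy(self) -> int:
        return len(self.labels) // 2

    @property
    def q_homologs(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, c in enumerate(self.labels) if c == "Q")

    @property
    def display(self) -> str:
        p = self.ploidy
        return "".join(self.labels[:p]) + " x " + "".join(self.labels[p:])

    def __str__(self) -> str:
        return f"{self.display} ({self.action})"


def class_predictor(state: AncestryState, configuration: QTLConfiguration) -> float:
    """Predicted genotypic value of a state under a configuration.

    Additive: Q-copy count (with multiplicity under DR, so values up to 2
    per parent); dominant: 1 if any Q copy is inherited, else 0.
    """
    q = set(configuration.q_homologs)
    count = sum(1 for h in state.origins if h in q)
    if configuration.action == "dominant":
        return 1.0 if count >= 1 else 0.0
    return float(count)


def predictor_vector(
    states: list[AncestryState], configuration: QTLConfiguration
) -> np.ndarray:
    return np.array([class_predictor(s, configuration) for s in states])


def _affine_key(vec: np.ndarray) -> bytes:
    """Canonical key of an integer predictor vector up to affine maps.

    Two configurations whose predictors are related by x -> a + b*x (b != 0)
    yield identical regression fits, so only one can ever be identified; the
    key is invariant under shift, positive integer scaling and sign flip.
    """
    iv = np.round(np.asarray(vec)).astype(np.int64)

    def norm(x: np.ndarray) -> bytes:
        x = x - x.min()
        g = int(np.gcd.reduce(x))
        if g > 1:
            x = x // g
        return x.tobytes()

    return min(norm(iv), norm(iv.max() - iv))


def model_catalogue(
    ploidy: int, actions=ACTIONS
) -> list[QTLConfiguration]:
    """All segregating bi-allelic QTL configurations, de-duplicated.

    Enumeration convention: all o/Q label vectors over the 2*ploidy homologs
    are crossed with the requested gene actions; configurations whose
    predictor is constant over the noDR state space (non-segregating) are
    dropped, and configurations with affinely equivalent predictor vectors
    over the noDR states are merged (they induce identical fits: e.g. the
    Q<->o complement of an additive model, or a single-Q dominant model,
    which matches single-Q additive when double reduction is excluded).
    The representative kept is additive before dominant, then fewest Q
    labels, then lexicographic.
    """
    if ploidy not in (4, 6):
        raise ValueError("model catalogue supports ploidy 4 or 6")
    states = enumerate_ibd_states(ploidy, allow_dr=False)
    groups: dict[bytes, list[QTLConfiguration]] = {}
    order: list[bytes] = []
    for action in actions:
        for labels in itertools.product("oQ", repeat=2 * ploidy):
            cfg = QTLConfiguration(labels=labels, action=action)
            vec = predictor_vector(states, cfg)
            if np.ptp(vec) == 0:
                continue  # non-segregating
            key = _affine_key(vec)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(cfg)

    def rank(cfg: QTLConfiguration):
        return (
            ACTIONS.index(cfg.action),
            cfg.labels.count("Q"),
            cfg.labels,
        )

    return [min(groups[k], key=rank) for k in order]


def class_means(
    y: np.ndarray, state_probs: np.ndarray, weight_floor_frac: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior-weighted per-state phenotype means at a locus.

    Returns ``(means, total_weights, included)``; states whose total weight
    is below ``weight_floor_frac * N`` are flagged excluded (their mean is
    NaN).
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(state_probs, dtype=float)
    tot = W.sum(axis=0)
    included = tot >= weight_floor_frac * len(y)
    if not included.any():
        raise ValueError("all states have (near-)zero posterior weight")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (W * y[:, None]).sum(axis=0) / tot
    means[~included] = np.nan
    return means, tot, included


def bic(rss: float, n: int, p: int) -> float:
    """BIC = n * ln(RSS / n) + p * ln(n) (natural log).

    A perfect fit (RSS = 0) returns -inf.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        return float("-inf")
    return n * np.log(rss / n) + p * np.log(n)


@dataclasses.dataclass
class ModelFit:
    """OLS fit of per-state phenotype means on a configuration predictor."""

    configuration: QTLConfiguration
    n: int
    p: int
    rss: float
    bic: float
    slope: float
    intercept: float

    @property
    def perfect(self) -> bool:
        return self.rss == 0.0

    @property
    def direction(self) -> str:
        return "+" if self.slope >= 0 else "-"


def select_model(
    means: np.ndarray,
    states: list[AncestryState],
    catalogue: list[QTLConfiguration] | None = None,
    included: np.ndarray | None = None,
    ploidy: int | None = None,
) -> list[ModelFit]:
    """Rank candidate QTL configurations by BIC (ascending).

    ``means`` are the per-state weighted phenotype means (NaN / excluded
    states are ignored); ``states`` must match the state space the weights
    were computed on (36 noDR or 100 DR in a tetraploid).
    """
    means = np.asarray(means, dtype=float)
    if ploidy is None:
        ploidy = max(max(s.origins) for s in states) // 2
    if catalogue is None:
        catalogue = model_catalogue(ploidy)
    if not catalogue:
        raise ValueError("empty model catalogue")
    if included is None:
        included = ~np.isnan(means)
    yv = means[included]
    n = int(included.sum())
    fits = []
    for cfg in catalogue:
        x = predictor_vector(states, cfg)[included]
        Z = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ beta
        rss = float(resid @ resid)
        if rss < 1e-12 * max(float(yv @ yv), 1.0):
            rss = 0.0
        fits.append(
            ModelFit(
                configuration=cfg,
                n=n,
                p=2,
                rss=rss,
                bic=bic(rss, n, 2),
                slope=float(beta[1]),
                intercept=float(beta[0]),
            )
        )
    fits.sort(key=lambda f: (f.bic, f.rss))
    return fits


def model_report(fits: list[ModelFit]) -> pd.DataFrame:
    """Tidy ranking table: ``rank config action p n RSS BIC``."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(fits) + 1),
            "config": [f.configuration.display for f in fits],
            "action": [f.configuration.action for f in fits],
            "p": [f.p for f in fits],
            "n": [f.n for f in fits],
            "RSS": [f.rss for f in fits],
            "BIC": [f.bic for f in fits],
            "direction": [f.direction for f in fits],
        }
    )
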