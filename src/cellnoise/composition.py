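"""Cell-type composition analysis.

Age-associated enrichment or depletion of cell types is tested with a
binomial GLM: for each cell type, the per-individual counts (N_ct, N_other)
are modelled on age group with a logit link, treating each individual as an
independent binomial replicate.  The exponentiated age coefficient is the
old/young odds ratio, and the inverse-logit fitted values give the expected
cell-type proportion per age group (the estimated-marginal-means analogue
for a two-group design).

Also here: the noisy-cell fraction at a noise cutoff, per-type median-noise
deltas between age groups, and the multiclass imbalance degree (ID) used to
characterize composition fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

__all__ = [
    "CompositionTable",
    "EnrichmentResult",
    "ImbalanceResult",
    "composition_table",
    "fit_enrichment",
    "fit_enrichment_all",
    "noisy_fraction",
    "delta_median_noise",
    "imbalance_degree",
]


@dataclass
class CompositionTable:
    """Per-individual cell-type counts: rows (individual, age_group), one
    column of N_ct per cell type, plus per-individual totals."""

    counts: pd.DataFrame  # index: (individual, age_group); columns: cell types
    cell_types: list

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class EnrichmentResult:
    """Old/young odds ratio with Wald uncertainty and expected proportions."""

    cell_type: str
    odds_ratio: float
    log_or_se: float
    p_value: float
    expected_prop_young: float
    expected_prop_old: float
    corrected: bool = False


@dataclass
class ImbalanceResult:
    """Multiclass imbalance degree (0 for perfectly balanced classes)."""

    id_value: float
    n_minority: int
    distance_kind: str


def composition_table(ds: ExpressionDataset) -> CompositionTable:
    """Tabulate cells per (individual, age_group) x cell type."""
    for c in ("cell_type", "individual", "age_group"):
        if c not in ds.cell_meta.columns:
            raise ValueError(f"cell_meta is missing required column '{c}'")
    ct = pd.crosstab(
        [ds.cell_meta["individual"], ds.cell_meta["age_group"]], ds.cell_meta["cell_type"]
    )
    ct.index.names = ["individual", "age_group"]
    return CompositionTable(counts=ct, cell_types=list(ct.columns))


def _pooled_2x2(tab: CompositionTable, cell_type: str) -> np.ndarray:
    """[[old_ct, old_other], [young_ct, young_other]] pooled over individuals."""
    age = tab.counts.index.get_level_values("age_group")
    n_ct = tab.counts[cell_type]
    n_other = tab.totals - n_ct
    out = np.zeros((2, 2))
    for i, grp in enumerate(("old", "young")):
        sel = age == grp
        out[i] = [n_ct[sel].sum(), n_other[sel].sum()]
    return out


def fit_enrichment(
    tab: CompositionTable, cell_type: str, quasi: bool = False
) -> EnrichmentResult:
    """Binomial GLM of (N_ct, N_other) on age group for one cell type.

    OR = exp(old coefficient), Wald p-value; expected proportions are the
    inverse-logit fitted values per age group.  If a pooled 2x2 margin is
    zero (perfect separation), the Haldane +0.5 continuity correction is
    applied to the pooled table instead, and the result is flagged.
    ``quasi=True`` rescales standard errors by the Pearson dispersion to
    absorb between-individual overdispersion.
    """
    import statsmodels.api as sm

    if cell_type not in tab.counts.columns:
        raise ValueError(f"unknown cell type '{cell_type}'")
    age = tab.counts.index.get_level_values("age_group")
    for grp in ("young", "old"):
        if not (age == grp).any():
            raise ValueError(f"no individuals in age group '{grp}'")
    n_ct = tab.counts[cell_type].to_numpy(dtype=float)
    n_other = (tab.totals - tab.counts[cell_type]).to_numpy(dtype=float)
    if n_ct.sum() == 0:
        raise ValueError(f"cell type '{cell_type}' absent from all individuals")
    pooled = _pooled_2x2(tab, cell_type)
    if (pooled == 0).any():
        p = pooled + 0.5
        log_or = float(np.log(p[0, 0] * p[1, 1] / (p[0, 1] * p[1, 0])))
        se = float(np.sqrt((1.0 / p).sum()))
        from scipy.stats import norm

        z = log_or / se
        return EnrichmentResult(
            cell_type=cell_type,
            odds_ratio=float(np.exp(log_or)),
            log_or_se=se,
            p_value=float(2 * norm.sf(abs(z))),
            expected_prop_young=float(p[1, 0] / p[1].sum()),
            expected_prop_old=float(p[0, 0] / p[0].sum()),
            corrected=True,
        )
    is_old = np.asarray(age == "old", dtype=float)
    exog = sm.add_constant(is_old)
    model = sm.GLM(np.column_stack([n_ct, n_other]), exog, family=sm.families.Binomial())
    fit = model.fit(scale="X2" if quasi else None)
    log_or = float(fit.params[1])
    se = float(fit.bse[1])
    eta_young, eta_old = float(fit.params[0]), float(fit.params[0] + fit.params[1])
    inv_logit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return EnrichmentResult(
        cell_type=cell_type,
        odds_ratio=float(np.exp(log_or)),
        log_or_se=se,
        p_value=float(fit.pvalues[1]),
        expected_prop_young=float(inv_logit(eta_young)),
        expected_prop_old=float(inv_logit(eta_old)),
        corrected=False,
    )


def fit_enrichment_all(tab: CompositionTable, quasi: bool = False) -> pd.DataFrame:
    """Run fit_enrichment for every cell type; one row per type."""
    rows = []
    for ct in tab.cell_types:
        r = fit_enrichment(tab, ct, quasi=quasi)
        rows.append(
            {
                "cell_type": r.cell_type,
                "odds_ratio": r.odds_ratio,
                "log_or_se": r.log_or_se,
                "p_value": r.p_value,
                "expected_prop_young": r.expected_prop_young,
                "expected_prop_old": r.expected_prop_old,
                "corrected": r.corrected,
            }
        )
    return pd.DataFrame(rows)


def noisy_fraction(noise: Sequence[float], cutoff: float = 0.2) -> float:
    """Fraction of cells with noise >= cutoff (boundary inclusive)."""
    noise = np.asarray(noise, dtype=float)
    noise = noise[~np.isnan(noise)]
    if len(noise) == 0:
        raise ValueError("empty noise vector")
    return float((noise >= cutoff).mean())


def delta_median_noise(
    noise: Sequence[float],
    cell_types: Sequence,
    age_groups: Sequence,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-cell-type median noise by age group and the old - young delta.

    Types with fewer than ``min_cells`` non-missing cells in either group are
    omitted.
    """
    df = pd.DataFrame(
        {"noise": np.asarray(noise, dtype=float), "cell_type": list(cell_types), "age_group": list(age_groups)}
    ).dropna(subset=["noise"])
    rows = []
    for ct, sub in df.groupby("cell_type", sort=True):
        young = sub.loc[sub["age_group"] == "young", "noise"]
        old = sub.loc[sub["age_group"] == "old", "noise"]
        if len(young) < min_cells or len(old) < min_cells:
            continue
        my, mo = float(young.median()), float(old.median())
        rows.append(
            {"cell_type": ct, "median_young": my, "median_old": mo, "delta": mo - my}
        )
    return pd.DataFrame(rows)


def impute_missing_delta(deltas: Sequence[float]) -> float:
    """Impute one missing delta as the mean of the observed ones."""
    deltas = np.asarray(deltas, dtype=float)
    deltas = deltas[~np.isnan(deltas)]
    if len(deltas) == 0:
        raise ValueError("no observed deltas to impute from")
    return float(deltas.mean())


def imbalance_degree(
    class_counts: Sequence[int], distance_kind: str = "euclidean"
) -> ImbalanceResult:
    """Multiclass imbalance degree (ID).

    With K classes, empirical distribution zeta, uniform e and m minority
    classes (proportion < 1/K), ID = d(zeta, e) / d(iota_m, e) + (m - 1),
    where iota_m is the most extreme distribution with exactly m minority
    classes: m classes at 0, K - m - 1 at 1/K, and one at (m + 1)/K.
    Balanced input gives 0.  Distances: euclidean or hellinger.
    """
    counts = np.asarray(class_counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    if np.any(counts < 0):
        raise ValueError("negative class counts")
    K = len(counts)
    zeta = counts / total
    e = np.full(K, 1.0 / K)

    if distance_kind == "euclidean":
        dist = lambda p, q: float(np.linalg.norm(p - q))
    elif distance_kind == "hellinger":
        dist = lambda p, q: float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)) / np.sqrt(2))
    else:
        raise ValueError("distance_kind must be 'euclidean' or 'hellinger'")

    m = int((zeta < 1.0 / K).sum())
    if m == 0:
        return ImbalanceResult(id_value=0.0, n_minority=0, distance_kind=distance_kind)
    iota = np.concatenate([np.zeros(m), np.full(K - m - 1, 1.0 / K), [(m + 1) / K]])
    denom = dist(iota, e)
    value = dist(zeta, e) / denom + (m - 1)
    return ImbalanceResult(id_value=float(value), n_minority=m, distance_kind=distance_kind)
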