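"""Per-animal aggregation and group statistics.

The animal, not the image or the plaque, is the statistical unit: plaque-
level metrics are pooled over all of an animal's images into one
:class:`MouseSummary` row, and conditions are compared by two-sided
unpaired t-test (Student by default, the convention of the graphing
software named in the source workflow; Welch available), or by two-way
ANOVA (condition × plaque class, type II sums of squares for unbalanced
designs) with Bonferroni-adjusted per-class contrasts for class fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import CLASSES, class_fractions
from .config import RunConfig
from .errors import InsufficientDataError, ValidationError


@dataclass
class ImageMeasurements:
    """Everything measured on one image, the input to per-animal pooling."""

    image_id: str
    animal_id: str
    condition: str
    area_mm2: float
    plaques: pd.DataFrame
    neurons: pd.DataFrame
    microglia_density_per_mm2: float = math.nan
    periplaque_aqp4_ratio: float = math.nan
    perivascular_aqp4_ratio: float = math.nan


@dataclass
class MouseSummary:
    animal_id: str
    condition: str
    n_plaques_analyzed: int = 0
    mean_plaque_size_um2: float = math.nan
    plaque_density_per_mm2: float = math.nan
    amyloid_load: float = math.nan
    frac_dense_core: float = math.nan
    frac_fibrillar: float = math.nan
    frac_mixed: float = math.nan
    mean_interior_enrichment: float = math.nan
    mean_periphery_enrichment: float = math.nan
    microglia_density_per_mm2: float = math.nan
    mean_coverage_fraction: float = math.nan
    fraction_abeta_positive_neurons: float = math.nan
    fraction_dystrophic_plaques: float = math.nan
    mean_periplaque_aqp4_ratio: float = math.nan
    mean_perivascular_aqp4_ratio: float = math.nan
    below_min_plaques: bool = False


@dataclass
class ComparisonResult:
    metric: str
    group_names: tuple
    group_means: tuple
    group_sems: tuple
    test_name: str
    statistic: float
    p_value: float
    stars: str
    degenerate: bool = False
    p_adjusted: Optional[float] = None


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan


def summarize_mouse(images: Sequence[ImageMeasurements], config: RunConfig) -> MouseSummary:
    """Pool an animal's images: plaque-level metrics averaged over all
    plaques pooled across images, densities area-weighted, missing metrics
    propagated as NaN."""
    if not images:
        raise ValidationError("summarize_mouse needs at least one image")
    animal = images[0].animal_id
    cond = images[0].condition
    plaques = pd.concat([im.plaques for im in images], ignore_index=True) if images else pd.DataFrame()
    if config.exclude_border_plaques and "on_border" in plaques.columns and len(plaques):
        plaques = plaques[~plaques["on_border"]].reset_index(drop=True)
    neurons = pd.concat([im.neurons for im in images], ignore_index=True)
    total_area = float(sum(im.area_mm2 for im in images))

    s = MouseSummary(animal_id=animal, condition=cond)
    n = len(plaques)
    s.n_plaques_analyzed = n
    s.plaque_density_per_mm2 = n / total_area
    if n:
        s.mean_plaque_size_um2 = float(plaques["area_um2"].mean())
        s.amyloid_load = float(plaques["area_um2"].sum()) / (total_area * 1e6)
        fr = class_fractions(list(plaques["plaque_class"]))
        s.frac_dense_core = fr["frac_dense_core"]
        s.frac_fibrillar = fr["frac_fibrillar"]
        s.frac_mixed = fr["frac_mixed"]
        for col, attr in (
            ("interior_enrichment", "mean_interior_enrichment"),
            ("periphery_enrichment", "mean_periphery_enrichment"),
            ("coverage_fraction", "mean_coverage_fraction"),
        ):
            if col in plaques.columns and plaques[col].notna().any():
                setattr(s, attr, float(plaques[col].mean(skipna=True)))
        if "is_dystrophic" in plaques.columns and plaques["is_dystrophic"].notna().any():
            s.fraction_dystrophic_plaques = float(plaques["is_dystrophic"].mean())
    else:
        s.amyloid_load = 0.0

    densities = np.array([im.microglia_density_per_mm2 for im in images], dtype=float)
    areas = np.array([im.area_mm2 for im in images], dtype=float)
    ok = ~np.isnan(densities)
    if ok.any():
        s.microglia_density_per_mm2 = float((densities[ok] * areas[ok]).sum() / areas[ok].sum())

    if len(neurons) and "puncta_count" in neurons.columns:
        near = neurons[neurons["distance_to_nearest_plaque_um"] <= config.neuron_search_radius_um]
        if len(near):
            s.fraction_abeta_positive_neurons = float(
                (near["puncta_count"] >= config.puncta_positive_threshold).mean()
            )

    for attr, col in (
        ("mean_periplaque_aqp4_ratio", "periplaque_aqp4_ratio"),
        ("mean_perivascular_aqp4_ratio", "perivascular_aqp4_ratio"),
    ):
        vals = np.array([getattr(im, col) for im in images], dtype=float)
        if (~np.isnan(vals)).any():
            setattr(s, attr, float(np.nanmean(vals)))

    s.below_min_plaques = n < config.min_plaques_per_mouse
    return s


def summaries_frame(summaries: Sequence[MouseSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def _metric_by_group(summaries, metric: str) -> Dict[str, np.ndarray]:
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    if metric not in df.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    out = {}
    for cond, grp in df.groupby("condition", sort=True):
        vals = grp[metric].to_numpy(dtype=float)
        out[str(cond)] = vals[~np.isnan(vals)]
    return out


def compare_groups(
    summaries,
    metric: str,
    test: str = "unpaired_t",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided unpaired t-test between two conditions on a per-animal
    metric.  ``equal_var=True`` gives the classical Student test; False the
    Welch variant.  Identical zero-variance groups are flagged degenerate."""
    if test != "unpaired_t":
        raise ValidationError(f"unsupported test {test!r}")
    groups = _metric_by_group(summaries, metric)
    if len(groups) != 2:
        raise InsufficientDataError(f"need exactly 2 conditions, got {sorted(groups)}")
    (na, a), (nb, b) = sorted(groups.items())
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(f"metric {metric!r}: each group needs >= 2 animals")
    degenerate = np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0
    if degenerate and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
        if math.isnan(p):  # zero pooled variance with separated means
            t = math.inf if np.mean(a) > np.mean(b) else -math.inf
            p = 0.0
    return ComparisonResult(
        metric=metric,
        group_names=(na, nb),
        group_means=(float(np.mean(a)), float(np.mean(b))),
        group_sems=(_sem(a), _sem(b)),
        test_name="Student t" if equal_var else "Welch t",
        statistic=t,
        p_value=p,
        stars=significance_stars(p),
        degenerate=bool(degenerate or not math.isfinite(t)),
    )


def bonferroni(p: float, k: int) -> float:
    """Bonferroni adjustment: min(1, k·p)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return min(1.0, k * p)


def compare_class_fractions(
    summaries, equal_var: bool = True
) -> Tuple[pd.DataFrame, List[ComparisonResult]]:
    """Two-way ANOVA (condition × plaque class, animals as replicates) on
    class fractions, plus Bonferroni-adjusted per-class condition contrasts.

    Classes absent in every animal are excluded with a warning.  Returns the
    type-II ANOVA table and one ComparisonResult per retained class.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    long = df.melt(
        id_vars=["animal_id", "condition"],
        value_vars=[f"frac_{c}" for c in CLASSES],
        var_name="plaque_class",
        value_name="fraction",
    ).dropna(subset=["fraction"])
    long["plaque_class"] = long["plaque_class"].str.removeprefix("frac_")
    keep = []
    for cls in CLASSES:
        sub = long[long["plaque_class"] == cls]
        if len(sub) == 0 or (sub["fraction"] == 0).all():
            warnings.warn(f"plaque class {cls!r} absent in all animals; excluded")
        else:
            keep.append(cls)
    long = long[long["plaque_class"].isin(keep)]
    if long["condition"].nunique() != 2 or not keep:
        raise InsufficientDataError("need 2 conditions and at least one observed class")
    model = smf.ols("fraction ~ C(condition) * C(plaque_class)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    k = len(keep)
    results = []
    for cls in keep:
        res = compare_groups(
            long[long["plaque_class"] == cls].rename(columns={"fraction": "value"}),
            "value",
            equal_var=equal_var,
        )
        res.metric = f"frac_{cls}"
        res.p_adjusted = bonferroni(res.p_value, k)
        res.stars = significance_stars(res.p_adjusted)
        results.append(res)
    return anova, results


def cumulative_distribution(values) -> pd.DataFrame:
    """ECDF of pooled per-plaque values: sorted values with step heights i/n."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("cumulative_distribution needs at least one value")
    if np.isnan(values).any():
        raise ValidationError("values contain NaN")
    x = np.sort(values)
    return pd.DataFrame({"value": x, "ecdf": np.arange(1, x.size + 1) / x.size})
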