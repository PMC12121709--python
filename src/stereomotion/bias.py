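"""Coarse-scale retinotopic-bias diagnostics.

Vertex selection (eccentricity 0.2-8 deg, pRF variance explained > 5%),
sub-ROI splits by eccentricity (central 0.2-4 deg vs edge 4-8 deg) and
polar angle (horizontal-meridian wedge +-30 deg vs the rest), BOLD group
means and HM-NHM differences, BOLD-vs-eccentricity fits with group
inference, and vertex-count-equated sub-ROI decoding-accuracy bias.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .decode import decode_features
from .preprocess import TrialMatrix
from .stats import TestResult, cohens_f2, wilcoxon_signed_rank
from .synth import VertexPopulation, hm_wedge_mask

logger = logging.getLogger(__name__)

ECC_FILTER = (0.2, 8.0)
VE_FILTER = 0.05
ECC_BOUND = 4.0
HM_HALF_WIDTH = 30.0
MIN_GROUP = 2


@dataclass
class SubRoiSplit:
    """Two disjoint vertex groups from an eccentricity or polar-angle split."""

    kind: str                      # "eccentricity" | "polar"
    group_a: np.ndarray            # central / HM vertex ids
    group_b: np.ndarray            # edge / NHM vertex ids
    boundary: float                # eccentricity bound or wedge half-width
    names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("split groups must be disjoint")

    @property
    def usable(self) -> bool:
        return min(self.group_a.size, self.group_b.size) >= MIN_GROUP

    @property
    def equated_count(self) -> int:
        return int(min(self.group_a.size, self.group_b.size))


@dataclass
class BiasReport:
    """Per-analysis bias summary fields (filled by the individual diagnostics)."""

    group_means: dict = dfield(default_factory=dict)   # % signal per group
    difference: float | None = None                    # HM-NHM (or A-B), % signal
    accuracy_bias: float | None = None                 # percentage points
    slope: float | None = None                         # % signal per deg
    test: TestResult | None = None
    meta: dict = dfield(default_factory=dict)


def filter_vertices(
    population: VertexPopulation,
    ecc_range: tuple[float, float] = ECC_FILTER,
    ve_min: float = VE_FILTER,
) -> np.ndarray:
    """Ids of vertices with eccentricity in ``ecc_range`` and VE > ``ve_min``."""
    tab = population.table
    ecc = tab["ecc"].to_numpy()
    keep = (ecc >= ecc_range[0]) & (ecc <= ecc_range[1]) & (tab["ve"].to_numpy() > ve_min)
    ids = np.flatnonzero(keep)
    if ids.size == 0:
        logger.warning("vertex filter left no vertices")
    return ids


def split_eccentricity(
    ids: np.ndarray,
    population: VertexPopulation,
    bound: float = ECC_BOUND,
) -> SubRoiSplit:
    """Central [0.2, bound) vs edge [bound, 8] split; the boundary goes to edge."""
    ids = np.asarray(ids, int)
    ecc = population.table["ecc"].to_numpy()[ids]
    central = ids[ecc < bound]
    edge = ids[ecc >= bound]
    split = SubRoiSplit("eccentricity", central, edge, bound, ("central", "edge"))
    if not split.usable:
        logger.warning("eccentricity split has a group with < %d vertices; "
                       "downstream analyses will skip it", MIN_GROUP)
    return split


def split_polar(
    ids: np.ndarray,
    population: VertexPopulation,
    half_width: float = HM_HALF_WIDTH,
) -> SubRoiSplit:
    """HM (within half_width of either horizontal meridian) vs NHM split."""
    ids = np.asarray(ids, int)
    polar = population.table["polar"].to_numpy()[ids]
    hm = hm_wedge_mask(polar, half_width)
    return SubRoiSplit("polar", ids[hm], ids[~hm], half_width, ("HM", "NHM"))


def bold_group_means(
    matrix: TrialMatrix,
    split: SubRoiSplit,
    condition=None,
    direction: str | None = None,
) -> BiasReport:
    """Mean amplitude per split group (over trials and vertices) and A-B difference.

    Expects a ``percent``-mode matrix so means are on the % -signal scale.
    """
    sub = matrix.select(condition=condition, direction=direction)
    report = BiasReport(meta={"kind": split.kind, "condition": condition})
    means = {}
    for name, ids in zip(split.names, (split.group_a, split.group_b)):
        if ids.size == 0:
            warnings.warn(f"empty {name} group: BOLD mean set to NaN",
                          RuntimeWarning, stacklevel=2)
            means[name] = float("nan")
        else:
            means[name] = float(sub.data[:, ids].mean())
    report.group_means = means
    report.difference = means[split.names[0]] - means[split.names[1]]
    return report


def eccentricity_slope(
    matrix: TrialMatrix,
    population: VertexPopulation,
    ids: np.ndarray | None = None,
    condition=None,
) -> float:
    """Least-squares slope of mean vertex amplitude against pRF eccentricity."""
    ids = np.arange(population.n_vertices) if ids is None else np.asarray(ids, int)
    sub = matrix.select(condition=condition)
    ecc = population.table["ecc"].to_numpy()[ids]
    if np.ptp(ecc) < 1e-12:
        raise ValueError("constant eccentricity: slope undefined")
    if ids.size < 3:
        raise ValueError("need at least 3 vertices to fit a slope")
    mean_amp = sub.data[:, ids].mean(axis=0)
    return float(np.polyfit(ecc, mean_amp, 1)[0])


def bold_eccentricity_fit(
    matrices: list[TrialMatrix],
    populations: list[VertexPopulation],
    ids_list: list[np.ndarray] | None = None,
    condition=None,
    method: str = "auto",
) -> BiasReport:
    """Per-participant eccentricity slopes with a group-level test.

    ``method="mixed"`` fits a random-slope mixed model (statsmodels
    MixedLM) of vertex amplitude on eccentricity and tests the fixed
    slope, also reporting Cohen's f^2 from nested OLS fits;
    ``"per_participant"`` runs the signed-rank test on the per-
    participant slopes; ``"auto"`` tries the mixed model and falls back.
    """
    if ids_list is None:
        ids_list = [None] * len(matrices)
    slopes = [eccentricity_slope(m, p, i, condition)
              for m, p, i in zip(matrices, populations, ids_list)]
    report = BiasReport(meta={"slopes": slopes, "condition": condition})
    report.slope = float(np.mean(slopes))
    if method in ("mixed", "auto"):
        try:
            report.test = _mixed_slope_test(matrices, populations, ids_list,
                                            condition, report)
            report.meta["method"] = "mixed"
            return report
        except Exception as err:  # noqa: BLE001 - fall back on any fit failure
            if method == "mixed":
                raise
            logger.warning("mixed-model fit failed (%s); using per-participant slopes", err)
    report.test = wilcoxon_signed_rank(np.asarray(slopes))
    report.meta["method"] = "per_participant"
    return report


def _mixed_slope_test(matrices, populations, ids_list, condition, report) -> TestResult:
    import statsmodels.api as sm
    from statsmodels.formula.api import mixedlm

    rows = []
    for pid, (m, p, ids) in enumerate(zip(matrices, populations, ids_list)):
        ids = np.arange(p.n_vertices) if ids is None else np.asarray(ids, int)
        sub = m.select(condition=condition)
        rows.append(pd.DataFrame({
            "amp": sub.data[:, ids].mean(axis=0),
            "ecc": p.table["ecc"].to_numpy()[ids],
            "participant": pid,
        }))
    data = pd.concat(rows, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mixedlm("amp ~ ecc", data, groups=data["participant"],
                      re_formula="~ecc").fit(reml=True)
    # Cohen's f^2 from nested fixed-effect OLS fits (with vs without eccentricity)
    full = sm.OLS(data["amp"], sm.add_constant(data["ecc"])).fit()
    reduced = sm.OLS(data["amp"], np.ones(len(data))).fit()
    try:
        report.meta["cohens_f2"] = cohens_f2(full.rsquared, max(0.0, reduced.rsquared))
    except ValueError:
        report.meta["cohens_f2"] = float("nan")
    return TestResult(float(fit.tvalues["ecc"]), float(fit.pvalues["ecc"]),
                      "mixedlm_slope", len(matrices))


def equated_subroi_decoding(
    matrix: TrialMatrix,
    split: SubRoiSplit,
    condition=None,
    n_resample: int = 500,
    n_boot: int = 100,
    seed: int | None = None,
    *,
    test_fraction: float = 0.10,
) -> BiasReport:
    """Decoding-accuracy bias between split groups with vertex-count equating.

    On each of ``n_resample`` draws the larger group is subsampled to
    the smaller group's vertex count and both groups are decoded; the
    bias is 100 x (mean accuracy of group A - group B) in percentage
    points, averaged over draws.
    """
    report = BiasReport(meta={"kind": split.kind, "condition": condition,
                              "names": split.names})
    if not split.usable:
        warnings.warn("a split group has < 2 vertices: skipping equated decoding",
                      RuntimeWarning, stacklevel=2)
        return report
    rng = np.random.default_rng(seed)
    sub = matrix.select(condition=condition)
    y = np.where(sub.labels["direction"].to_numpy() == "toward", 1, -1)
    k = split.equated_count
    acc = {name: [] for name in split.names}
    for _ in range(n_resample):
        for name, ids in zip(split.names, (split.group_a, split.group_b)):
            take = ids if ids.size == k else rng.choice(ids, size=k, replace=False)
            res = decode_features(
                sub.data[:, take], y, n_boot=n_boot,
                seed=int(rng.integers(0, 2**31)), test_fraction=test_fraction,
            )
            acc[name].append(res.mean_accuracy)
    means = {name: float(np.mean(v)) for name, v in acc.items()}
    report.group_means = means
    report.accuracy_bias = 100.0 * (means[split.names[0]] - means[split.names[1]])
    report.meta["equated_count"] = k
    return report
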