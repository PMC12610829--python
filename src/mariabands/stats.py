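"""Group-separation diagnostics for a three-band severity classification.

Given the five analysis variables per segment (T2 SI ratio, wall
thickness, MaRIA, DWI MaRIA, ADC) and a grouping into inactive/active/
severe, this module reproduces the standard battery used to judge how
well a classification scheme separates the bands:

* per-group descriptives (mean, SD, min/max, CV, 95% t-CI of the mean,
  bias-corrected skewness G1 and excess kurtosis G2, normality p-value);
* MANOVA via Wilks' lambda with Rao's F approximation;
* one-way ANOVA per variable, and pairwise two-tailed t-tests summarized
  with the *1/*2 marker convention (*1: the middle-valued group differs
  from the lowest; *2: the extreme group differs from both others);
* per-variable discriminant contributions (Fisher ratios normalized to
  sum to 100%);
* within-group homogeneity: resubstitution accuracy of a pooled-
  covariance, equal-prior linear discriminant classifier;
* the pairwise Mahalanobis distance matrix on the pooled within-group
  covariance (reported as D by default; D**2 behind a flag).

Two schemes analysed on the same cohort can then be compared pairwise
(:func:`compare_schemes`): larger Mahalanobis distances mean cleaner
separation of the severity bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, EmptyGroupError, SingularCovarianceError

#: The five analysis variables, in fixed reporting order.
ANALYSIS_VARIABLES = ("t2_ratio", "wall_thickness", "maria", "dwi_maria", "adc")

GROUP_NAMES = ("inactive", "active", "severe")


def group_names(n_groups: int) -> tuple:
    """Clinical band names for 3 groups, generic band names otherwise."""
    if n_groups == 3:
        return GROUP_NAMES
    return tuple(f"band_{i + 1}" for i in range(n_groups))

MARKER_NONE, MARKER_STAR1, MARKER_STAR2 = "", "*1", "*2"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100 * sd / mean."""
    if mean == 0:
        raise DegenerateInputError("CV undefined for zero mean")
    return 100.0 * sd / mean


def t_confidence_interval(mean: float, sd: float, n: int, confidence: float = 0.95):
    """t-based CI of the mean from summary statistics: mean +/- t * sd / sqrt(n)."""
    if n < 2:
        raise DegenerateInputError("CI of the mean needs n >= 2")
    half = sps.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sd / np.sqrt(n)
    return mean - half, mean + half


def homogeneity_percent(n_correct: int, n_total: int) -> float:
    """Reclassification consistency as a percentage, rounded to 2 decimals."""
    if n_total <= 0:
        raise EmptyGroupError("homogeneity undefined for an empty group")
    return round_half_away(100.0 * n_correct / n_total, 2)


@dataclass(frozen=True)
class GroupDescriptives:
    """One row of a descriptive-statistics table (one variable, one group)."""

    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    cv: float
    ci_low: float
    ci_high: float
    skewness: float | None
    kurtosis: float | None
    normality_p: float | None
    degenerate: bool = False


def describe_group(values, confidence: float = 0.95,
                   normality_test: str = "shapiro") -> GroupDescriptives:
    """Descriptive statistics and a normality p-value for one group.

    Skewness is the adjusted Fisher-Pearson G1 (n >= 3), kurtosis the
    bias-corrected excess G2 (n >= 4); both are None below those sizes.
    Constant or single-value input yields degenerate output (sd 0, CV 0,
    CI collapsed to the mean) flagged via ``degenerate``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise EmptyGroupError("cannot describe an empty group")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n >= 2 else 0.0
    if n < 2 or sd == 0:
        return GroupDescriptives(
            n=n, mean=mean, sd=0.0,
            minimum=float(values.min()), maximum=float(values.max()),
            cv=0.0, ci_low=mean, ci_high=mean,
            skewness=None, kurtosis=None, normality_p=None,
            degenerate=True,
        )
    ci_low, ci_high = t_confidence_interval(mean, sd, n, confidence)
    skew = float(sps.skew(values, bias=False)) if n >= 3 else None
    kurt = float(sps.kurtosis(values, bias=False)) if n >= 4 else None
    if normality_test == "shapiro" and n >= 3:
        normality_p = float(sps.shapiro(values).pvalue)
    elif normality_test == "normaltest" and n >= 8:
        normality_p = float(sps.normaltest(values).pvalue)
    else:
        normality_p = None
    return GroupDescriptives(
        n=n, mean=mean, sd=sd,
        minimum=float(values.min()), maximum=float(values.max()),
        cv=cv_percent(mean, sd), ci_low=ci_low, ci_high=ci_high,
        skewness=skew, kurtosis=kurt, normality_p=normality_p,
    )


def _scatter_matrices(groups):
    """Within- and between-group scatter matrices for a list of (n_g, p) arrays."""
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    p = groups[0].shape[1]
    N = sum(len(g) for g in groups)
    grand = np.vstack(groups).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        if len(g) == 0:
            raise EmptyGroupError("scatter matrices need non-empty groups")
        m = g.mean(axis=0)
        centered = g - m
        W += centered.T @ centered
        d = (m - grand)[:, None]
        B += len(g) * (d @ d.T)
    return W, B, N


def manova_wilks(groups):
    """Wilks' lambda with Rao's F approximation for g groups of p variables.

    Returns ``(lambda, F, (df1, df2), p)`` where
    lambda = det(W) / det(W + B). For p = 1 the statistic reduces
    exactly to the one-way ANOVA F.
    """
    W, B, N = _scatter_matrices(groups)
    g = len(groups)
    p = W.shape[0]
    if N <= p + g:
        raise ValueError(f"need total n > variables + groups ({p + g}), got {N}")
    det_w = np.linalg.det(W)
    det_t = np.linalg.det(W + B)
    if det_w <= 0 or not np.isfinite(det_w):
        raise SingularCovarianceError(
            "singular within-group scatter; drop a linearly dependent or "
            "constant variable"
        )
    lam = float(det_w / det_t)
    q = g - 1
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    m = N - 1 - (p + q + 1) / 2.0
    df1 = p * q
    df2 = m * s - (p * q) / 2.0 + 1
    lam_s = lam ** (1.0 / s)
    F = (1 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return lam, float(F), (float(df1), float(df2)), pval


def anova_oneway(groups):
    """Classical one-way ANOVA on 1-D groups; returns (F, p).

    Zero within-group variance with distinct means is reported as
    F = inf, p = 0 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = N - len(groups)
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (float("inf"), 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


def pairwise_ttest(a, b, welch: bool = False) -> float:
    """Two-tailed two-sample t-test p-value (pooled variance by default)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                        equal_var=not welch)
    return float(res.pvalue)


def pairwise_markers(groups, alpha: float = 0.05, welch: bool = False):
    """The *1/*2 marker convention for three groups of one variable.

    Groups arrive in severity order. They are ranked by mean (ties
    broken by severity position): the middle-valued group earns *1 when
    it differs from the lowest-valued group at p < alpha; the
    extreme-valued group earns *2 when it differs from both others (or
    *1 when it differs from the middle group only). Returns one marker
    per input group, in input order.
    """
    if len(groups) != 3:
        raise ValueError("marker convention is defined for exactly 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    means = [g.mean() for g in groups]
    low, mid, high = sorted(range(3), key=lambda i: (means[i], i))
    markers = [MARKER_NONE, MARKER_NONE, MARKER_NONE]
    if pairwise_ttest(groups[mid], groups[low], welch) < alpha:
        markers[mid] = MARKER_STAR1
    p_hl = pairwise_ttest(groups[high], groups[low], welch)
    p_hm = pairwise_ttest(groups[high], groups[mid], welch)
    if p_hl < alpha and p_hm < alpha:
        markers[high] = MARKER_STAR2
    elif p_hm < alpha:
        markers[high] = MARKER_STAR1
    return tuple(markers)


def pooled_covariance(groups):
    """Pooled within-group covariance S = W / (N - g)."""
    W, _, N = _scatter_matrices(groups)
    g = len(groups)
    if N - g < 1:
        raise ValueError("pooled covariance needs N > number of groups")
    return W / (N - g)


def mahalanobis_matrix(groups, squared: bool = False) -> np.ndarray:
    """Pairwise Mahalanobis distances between group mean vectors.

    D(a, b) = sqrt((m_a - m_b)' S_pooled^-1 (m_a - m_b)); symmetric with
    a zero diagonal. ``squared=True`` returns D**2.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    S = pooled_covariance(groups)
    try:
        chol = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("pooled covariance is singular") from exc
    means = [g.mean(axis=0) for g in groups]
    g = len(groups)
    D = np.zeros((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            y = np.linalg.solve(chol, means[a] - means[b])
            d2 = float(y @ y)
            D[a, b] = D[b, a] = d2 if squared else np.sqrt(d2)
    return D


def lda_homogeneity(groups):
    """Resubstitution homogeneity of a linear discriminant classifier.

    Fits the pooled-covariance, equal-prior linear discriminant rule on
    the grouped data and reclassifies the same observations. Returns a
    list of (n_correct, n_total, percent) per group, percent rounded to
    2 decimals; ties in discriminant score go to the lower group index.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    S = pooled_covariance(groups)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("pooled covariance is singular") from exc
    means = [g.mean(axis=0) for g in groups]
    weights = [S_inv @ m for m in means]
    consts = [-0.5 * m @ S_inv @ m for m in means]
    out = []
    for gi, g in enumerate(groups):
        scores = np.column_stack([g @ w + c for w, c in zip(weights, consts)])
        assigned = np.argmax(scores, axis=1)  # argmax takes lowest index on ties
        n_correct = int(np.sum(assigned == gi))
        out.append((n_correct, len(g), homogeneity_percent(n_correct, len(g))))
    return out


def da_contributions(groups) -> np.ndarray:
    """Per-variable discriminant contributions in percent (sum to 100).

    Each variable's Fisher discrimination ratio (between-group sum of
    squares over within-group sum of squares for the given grouping) is
    normalized so the contributions sum to exactly 100.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    W, B, _ = _scatter_matrices(groups)
    ssw = np.diag(W)
    ssb = np.diag(B)
    if np.any(ssw <= 0):
        raise DegenerateInputError(
            "zero within-group variance for at least one variable"
        )
    ratios = ssb / ssw
    total = ratios.sum()
    if total == 0:
        raise DegenerateInputError("no between-group variation in any variable")
    return 100.0 * ratios / total


@dataclass
class SeparationReport:
    """Full separation battery for one classification scheme on one cohort."""

    scheme: str
    index_kind: str
    variables: tuple
    group_names: tuple
    group_sizes: tuple
    descriptives: dict            # group name -> variable -> GroupDescriptives
    wilks_lambda: float
    manova_f: float
    manova_df: tuple
    manova_p: float
    anova: dict                   # variable -> (F, p)
    markers: dict                 # variable -> marker per group (severity order)
    contributions: dict           # variable -> percent
    homogeneity: list             # per group (n_correct, n_total, percent)
    mahalanobis: np.ndarray
    squared_distances: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mahalanobis"] = np.asarray(self.mahalanobis).tolist()
        return d


def build_separation_report(frame, labels, scheme: str, index_kind: str,
                            variables=ANALYSIS_VARIABLES,
                            confidence: float = 0.95,
                            normality_test: str = "shapiro",
                            alpha: float = 0.05, welch: bool = False,
                            squared_distances: bool = False) -> SeparationReport:
    """Run the whole battery for one grouping of an indexed cohort.

    ``frame`` is an indexed cohort frame containing the analysis
    variables; ``labels`` are severity bands (0 inactive, 1 active,
    2 severe) aligned with its rows, or generic band ids 0..g-1 for a
    non-standard band count. All bands must be non-empty; the pairwise
    marker convention is only defined (and only reported) for 3 bands.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(frame):
        raise ValueError("labels must align with the cohort rows")
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValueError(f"cohort frame lacks analysis variable(s): {missing}")
    n_groups = int(labels.max()) + 1 if len(labels) else 0
    if n_groups < 2:
        raise ValueError("need at least 2 bands to analyse separation")
    names = group_names(n_groups)
    X = frame.loc[:, list(variables)].to_numpy(dtype=float)
    group_matrices = [X[labels == g] for g in range(n_groups)]
    sizes = tuple(len(g) for g in group_matrices)
    if min(sizes) == 0:
        empty = names[sizes.index(0)]
        raise EmptyGroupError(f"scheme '{scheme}' produced an empty '{empty}' group")

    descriptives = {
        name: {
            var: describe_group(g[:, j], confidence, normality_test)
            for j, var in enumerate(variables)
        }
        for name, g in zip(names, group_matrices)
    }
    lam, F, df, p = manova_wilks(group_matrices)
    anova = {}
    markers = {}
    # Singleton bands (possible under chaining-prone single link) cannot
    # support ANOVA or t-tests; those cells degrade to NaN / no marker.
    testable = min(sizes) >= 2
    for j, var in enumerate(variables):
        cols = [g[:, j] for g in group_matrices]
        anova[var] = anova_oneway(cols) if testable else (float("nan"), float("nan"))
        if n_groups == 3:
            markers[var] = (pairwise_markers(cols, alpha=alpha, welch=welch)
                            if testable else (MARKER_NONE,) * 3)
    contrib = da_contributions(group_matrices)
    return SeparationReport(
        scheme=scheme,
        index_kind=index_kind,
        variables=tuple(variables),
        group_names=names,
        group_sizes=sizes,
        descriptives=descriptives,
        wilks_lambda=lam,
        manova_f=F,
        manova_df=df,
        manova_p=p,
        anova=anova,
        markers=markers,
        contributions={var: float(c) for var, c in zip(variables, contrib)},
        homogeneity=lda_homogeneity(group_matrices),
        mahalanobis=mahalanobis_matrix(group_matrices, squared=squared_distances),
        squared_distances=squared_distances,
    )


#: The three group pairs of a 3-band scheme, in reporting order.
GROUP_PAIRS = ((0, 1), (0, 2), (1, 2))


def compare_schemes(report_a: SeparationReport, report_b: SeparationReport) -> dict:
    """Side-by-side pairwise Mahalanobis distances for two schemes.

    Both reports must come from the same cohort (same total n and
    variables). Returns per-pair distances, the b/a ratios, and whether
    scheme b separates more widely in every pair.
    """
    if report_a.variables != report_b.variables:
        raise ValueError("reports analyse different variable sets")
    if sum(report_a.group_sizes) != sum(report_b.group_sizes):
        raise ValueError("reports analyse cohorts of different size")
    if report_a.squared_distances != report_b.squared_distances:
        raise ValueError("reports mix D and D**2 distances")
    if report_a.group_names != report_b.group_names:
        raise ValueError("reports have different band structures")
    names = report_a.group_names
    pairs = GROUP_PAIRS if len(names) == 3 else tuple(
        (a, b) for a in range(len(names)) for b in range(a + 1, len(names))
    )
    rows = []
    all_larger = True
    for a, b in pairs:
        da = float(report_a.mahalanobis[a, b])
        db = float(report_b.mahalanobis[a, b])
        rows.append({
            "pair": f"{names[a]} vs {names[b]}",
            report_a.scheme: da,
            report_b.scheme: db,
            "ratio": db / da if da > 0 else float("inf"),
        })
        all_larger &= db > da
    return {
        "scheme_a": report_a.scheme,
        "scheme_b": report_b.scheme,
        "pairs": rows,
        "b_larger_in_all_pairs": bool(all_larger),
    }
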