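"""The full QICAR screen: endpoint x group x descriptor LTS grid.

Every cardiovascular endpoint is regressed on every descriptor separately
within the s-block and transition strata (descriptor collinearity rules out
multivariate fits, so each cell is univariate).  Cells join the ln inference
scores to descriptor values over the ions available for that endpoint, pick
the trim count from the default breakdown formula (or a per-cell override),
fit exact LTS, and attach reweighted post-LTS inference.  Significance is
Bonferroni-controlled: the working threshold is the exact quotient
alpha / m (0.05 / 16 = 0.003125), displayed rounded to 0.003.

The slope standardization divides (and, for completeness, multiplies) by the
IQR of the descriptor over *all* ions of the group carrying that descriptor
— the full property distribution, not just the endpoint-available ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ctd_scores import DiseaseScoreSet, ENDPOINTS, log_scores
from .ion_properties import DESCRIPTORS, PropertyTable, iqr_of_property
from .robust_regression import RobustFit, fit_inference, lts_fit, trim_count

GROUPS = ("s-block", "transition")
MIN_POINTS = 4  # cells with fewer joined ions are skipped, not fitted


def bonferroni_alpha(alpha: float, m_tests: int) -> float:
    """Exact per-test level alpha / m for a Bonferroni correction."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"overall alpha must lie in (0, 1), got {alpha}")
    if m_tests < 1:
        raise ValueError(f"number of tests must be >= 1, got {m_tests}")
    return alpha / m_tests


@dataclass
class CellResult:
    """Outcome of one (endpoint, group, property) cell of the grid."""

    endpoint: str
    group: str
    property: str
    status: str                    # "fit" | "skipped" | "failed"
    reason: str = ""
    fit: RobustFit | None = None
    significant: bool = False
    rank: int | None = None        # R^2 rank within (endpoint, group), 1 = best


@dataclass
class ScreenResult:
    """All 5 x 2 x 16 cells of a screen plus the thresholds used."""

    cells: list[CellResult]
    alpha: float
    m_tests: int
    corrected_alpha: float
    iqr_convention: str = "divide"
    config: dict = field(default_factory=dict)

    def cell(self, endpoint: str, group: str, prop: str) -> CellResult:
        for c in self.cells:
            if (c.endpoint, c.group, c.property) == (endpoint, group, prop):
                return c
        raise KeyError((endpoint, group, prop))

    @property
    def fitted(self) -> list[CellResult]:
        return [c for c in self.cells if c.status == "fit"]

    @property
    def significant(self) -> list[CellResult]:
        return [c for c in self.cells if c.significant]

    def all_fits_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            f = c.fit
            std = None
            if f is not None:
                std = f.std_slope_divide if self.iqr_convention == "divide" else f.std_slope_multiply
            rows.append({
                "endpoint": c.endpoint, "group": c.group, "property": c.property,
                "status": c.status, "reason": c.reason,
                "n": f.n if f else None, "n_trim": f.n_trim if f else None,
                "slope": f.slope if f else None,
                "intercept": f.intercept if f else None,
                "std_slope": std,
                "std_slope_divide": f.std_slope_divide if f else None,
                "std_slope_multiply": f.std_slope_multiply if f else None,
                "property_iqr": f.property_iqr if f else None,
                "se": f.se if f else None, "p_value": f.p_value if f else None,
                "r_squared": f.r_squared if f else None,
                "objective": f.objective if f else None,
                "retained_ions": ",".join(map(str, f.retained)) if f else "",
                "significant": c.significant, "r2_rank": c.rank,
            })
        return pd.DataFrame(rows)

    def significant_frame(self) -> pd.DataFrame:
        """Significant cells ordered by descending R^2 within endpoint/group."""
        df = self.all_fits_frame()
        df = df[df["significant"]].copy()
        df = df.sort_values(["endpoint", "group", "r_squared"],
                            ascending=[True, True, False])
        return df.reset_index(drop=True)

    def significance_matrix(self) -> pd.DataFrame:
        return significance_matrix(self)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.all_fits_frame().to_csv(outdir / "all_fits.tsv", sep="\t", index=False)
        self.significant_frame().to_csv(outdir / "significant.tsv", sep="\t", index=False)
        self.significance_matrix().to_csv(outdir / "significance_matrix.tsv", sep="\t")


def run_screen(scores: DiseaseScoreSet, props: PropertyTable,
               alpha: float = 0.05, correction: str = "per-cellset",
               ntrim_overrides: dict | None = None,
               iqr_convention: str = "divide",
               iqr_method: str = "linear",
               inference_convention: str = "reweighted",
               endpoints=None, properties=None) -> ScreenResult:
    """Fit the whole endpoint x group x descriptor grid.

    *correction* is ``"per-cellset"`` (Bonferroni over the 16 descriptors
    tested within each endpoint-group, the default) or ``"global"`` (over
    all endpoint x group x descriptor cells).  *ntrim_overrides* maps
    (endpoint, group, property) -> n_trim to reproduce specific published
    rows that deviate from the default breakdown formula.  Every cell is
    recorded: fit, skipped (with reason) or failed — never silently dropped.
    """
    if iqr_convention not in ("divide", "multiply"):
        raise ValueError("iqr_convention must be 'divide' or 'multiply'")
    endpoints = list(ENDPOINTS if endpoints is None else endpoints)
    properties = list(DESCRIPTORS if properties is None else properties)
    overrides = ntrim_overrides or {}

    m = len(properties) if correction == "per-cellset" else (
        len(endpoints) * len(GROUPS) * len(properties))
    corrected = bonferroni_alpha(alpha, m)

    # per-(group, property) IQR of the full group distribution, shared by all
    # endpoints; per-(endpoint, group) ln-score join, shared by all properties
    iqr_cache: dict[tuple[str, str], float | None] = {}
    for group in GROUPS:
        group_ions = props.ions_in_group(group)
        for prop in properties:
            try:
                iqr_cache[(group, prop)] = iqr_of_property(
                    props.values_of(prop, group_ions), method=iqr_method)
            except (ValueError, KeyError):
                iqr_cache[(group, prop)] = None

    cells: list[CellResult] = []
    for endpoint in endpoints:
        for group in GROUPS:
            try:
                lny = log_scores(scores, endpoint, group)
            except ValueError as exc:
                lny, join_err = None, str(exc)
            else:
                join_err = ""
            for prop in properties:
                cells.append(_fit_cell(props, lny, join_err, endpoint, group,
                                       prop, corrected, overrides,
                                       iqr_cache[(group, prop)],
                                       inference_convention))
            _rank_cellset(cells, endpoint, group)
    return ScreenResult(cells=cells, alpha=alpha, m_tests=m,
                        corrected_alpha=corrected, iqr_convention=iqr_convention,
                        config={"correction": correction, "iqr_method": iqr_method,
                                "inference_convention": inference_convention,
                                "ntrim_overrides": {" | ".join(k): v
                                                    for k, v in overrides.items()}})


def _fit_cell(props, lny, join_err, endpoint, group, prop, corrected_alpha,
              overrides, iqr, inference_convention="reweighted") -> CellResult:
    base = CellResult(endpoint=endpoint, group=group, property=prop, status="skipped")
    if lny is None:
        base.reason = join_err
        return base
    if prop not in props.frame.columns:
        base.reason = f"descriptor {prop!r} absent from property table"
        return base
    xvals = props.values_of(prop, [i for i in lny.index if i in props])
    common = [i for i in lny.index if i in xvals.index]
    n = len(common)
    if n < MIN_POINTS:
        base.reason = f"only {n} joined ions (< {MIN_POINTS})"
        return base

    key = (endpoint, group, prop)
    if key in overrides:
        h = n - int(overrides[key])
        if h < 3:
            base.status, base.reason = "failed", f"override n_trim={overrides[key]} leaves h={h}"
            return base
    else:
        h, _ = trim_count(n)

    x = xvals[common].to_numpy(dtype=float)
    y = lny[common].to_numpy(dtype=float)
    ions = common
    try:
        fit = lts_fit(x, y, h, labels=ions)
    except (ValueError, ZeroDivisionError) as exc:
        base.status, base.reason = "failed", str(exc)
        return base

    fit = fit_inference(fit, x, y, property_iqr=iqr, labels=ions,
                        convention=inference_convention)
    fit.endpoint, fit.group, fit.property = endpoint, group, prop
    significant = fit.p_value is not None and fit.p_value < corrected_alpha
    return CellResult(endpoint=endpoint, group=group, property=prop,
                      status="fit", fit=fit, significant=significant)


def _rank_cellset(cells, endpoint, group) -> None:
    subset = [c for c in cells
              if c.endpoint == endpoint and c.group == group and c.status == "fit"
              and c.fit is not None and c.fit.r_squared is not None]
    for rank, c in enumerate(sorted(subset, key=lambda c: -c.fit.r_squared), start=1):
        c.rank = rank


def significance_matrix(result: ScreenResult, dash: str = "—") -> pd.DataFrame:
    """Property x endpoint table listing the groups significant in each cell."""
    endpoints = list(dict.fromkeys(c.endpoint for c in result.cells)) or list(ENDPOINTS)
    properties = list(dict.fromkeys(c.property for c in result.cells)) or list(DESCRIPTORS)
    mat = pd.DataFrame(dash, index=pd.Index(properties, name="property"),
                       columns=endpoints)
    for c in result.cells:
        if not c.significant:
            continue
        cur = mat.loc[c.property, c.endpoint]
        mat.loc[c.property, c.endpoint] = c.group if cur == dash else f"{cur}, {c.group}"
    return mat


def scatter_data(scores: DiseaseScoreSet, props: PropertyTable,
                 prop: str = "AN") -> dict[str, pd.DataFrame]:
    """Per-endpoint tidy (ion, group, x, ln_score) frames for plotting."""
    out = {}
    for endpoint in scores.endpoints:
        rows = []
        for group in GROUPS:
            try:
                lny = log_scores(scores, endpoint, group)
            except ValueError:
                continue
            xvals = props.values_of(prop, [i for i in lny.index if i in props])
            for ion in lny.index:
                if ion in xvals.index:
                    rows.append((ion, group, xvals[ion], lny[ion]))
        out[endpoint] = pd.DataFrame(rows, columns=["ion", "group", prop, "ln_score"])
    return out
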