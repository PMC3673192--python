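"""Robustness layers around the LTS screen.

Three independent checks back up the screening results, all of which matter
because each cell has only 4-10 ions:

1. Monte Carlo outlier-injection simulation — regenerate ln-scores from the
   fitted line with normal noise, displace a few points beyond 3 sigma
   (one more than LTS trimmed in the original fit, so the contamination
   strictly exceeds what the fit claimed to remove), refit LTS per
   replicate, and compare slope centrality/spread with the original fit.
2. Cross-estimator comparison — LTS against the M / S / MM families; large
   pairwise slope disagreement flags a fragile cell.
3. Held-out validation — predict ln-scores for ions outside the model
   (Al(III), Cr(VI), V(V) in the study design) and summarize the misfit as
   a relative L2 error norm, ||pred - obs||_2 / ||obs||_2.

Injected outliers are placed at exactly +/-3 sigma from their generating
means (sign chosen by a fair coin); the contamination *count* is what
exceeds the original fit's trim count, defaulting to one more than the
points LTS trimmed.  All randomness flows from a single root seed through
per-replicate substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctd_scores import DiseaseScoreSet
from .ion_properties import PropertyTable
from .robust_regression import (ConvergenceError, RobustFit, fit_inference,
                                lts_fit, robust_fit, trim_count)

ESTIMATORS = ("LTS", "M", "S", "MM")


# ---------------------------------------------------------------------------
# Monte Carlo

def simulate_replicate(beta0: float, beta1: float, sigma: float, x,
                       n_outliers: int, seed) -> np.ndarray:
    """One simulated ln-score vector: Normal(beta0 + beta1*x, sigma) with
    *n_outliers* randomly chosen points set to mean +/- 3 sigma (random
    sign).  *seed* may be an int or a numpy SeedSequence/Generator."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n_outliers > n:
        raise ValueError(f"n_outliers={n_outliers} exceeds n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = beta0 + beta1 * x
    y = rng.normal(mean, sigma)
    if n_outliers > 0:
        idx = rng.choice(n, size=n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        y[idx] = mean[idx] + signs * 3.0 * sigma
    return y


@dataclass
class SimulationSummary:
    """Slope-recovery statistics over the Monte Carlo replicates."""

    replicates: int
    n_failed: int
    beta0: float
    beta1: float
    sigma: float
    n_outliers: int
    slope_mean: float
    slope_sd: float
    relative_deviation_pct: float      # |mean slope - beta1| / |beta1| * 100
    mean_reported_se: float | None     # average per-replicate LTS-refit SE
    se_ratio: float | None             # empirical SD / mean reported SE

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.replicates


def monte_carlo(beta0: float, beta1: float, sigma: float, x,
                n_outliers: int, replicates: int, seed: int,
                h: int | None = None,
                balance_outliers: bool = False) -> SimulationSummary:
    """LTS slope-recovery simulation.

    Each replicate draws ln-scores via :func:`simulate_replicate` from an
    independent substream of *seed*, refits LTS with the default trim count
    for n (or explicit *h*), and records the slope and its reported SE.
    Failed fits are counted and excluded.

    With ``balance_outliers=True`` the outlier positions and signs are
    stratified — the replicates cycle through a seeded shuffle of all
    (position set, sign pattern) configurations instead of drawing each
    independently.  Marginally every replicate keeps the prescribed
    contamination distribution; jointly the strata are balanced, which
    removes the between-configuration component from the Monte Carlo error
    of the mean slope (a standard variance-reduction device; the mean is
    still estimated, not derived).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    x = np.asarray(x, dtype=float)
    if h is None:
        h, _ = trim_count(x.size)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(replicates + 1)

    configs = None
    if balance_outliers and n_outliers > 0:
        import itertools
        combos = list(itertools.combinations(range(x.size), n_outliers))
        signs = list(itertools.product((-1.0, 1.0), repeat=n_outliers))
        all_configs = [(c, s) for c in combos for s in signs]
        order_rng = np.random.default_rng(streams[-1])
        reps_per_cycle = len(all_configs)
        order = np.concatenate([
            order_rng.permutation(reps_per_cycle)
            for _ in range(replicates // reps_per_cycle + 1)])[:replicates]
        configs = [all_configs[i] for i in order]

    mean_line = beta0 + beta1 * x
    slopes, ses = [], []
    n_failed = 0
    for rep, stream in enumerate(streams[:replicates]):
        rng = np.random.default_rng(stream)
        if configs is None:
            y = simulate_replicate(beta0, beta1, sigma, x, n_outliers, rng)
        else:
            y = rng.normal(mean_line, sigma)
            idx, sgn = configs[rep]
            for i, s in zip(idx, sgn):
                y[i] = mean_line[i] + s * 3.0 * sigma
        try:
            fit = lts_fit(x, y, h)
            fit = fit_inference(fit, x, y)
        except (ValueError, ZeroDivisionError):
            n_failed += 1
            continue
        slopes.append(fit.slope)
        if fit.se is not None:
            ses.append(fit.se)

    slopes = np.asarray(slopes)
    if slopes.size == 0:
        raise RuntimeError("every Monte Carlo replicate failed to fit")
    mean = float(slopes.mean())
    sd = float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0
    rel_dev = abs(mean - beta1) / abs(beta1) * 100.0 if beta1 != 0 else abs(mean) * 100.0
    mean_se = float(np.mean(ses)) if ses else None
    ratio = (sd / mean_se) if (mean_se and mean_se > 0) else None
    return SimulationSummary(
        replicates=replicates, n_failed=n_failed, beta0=beta0, beta1=beta1,
        sigma=sigma, n_outliers=n_outliers, slope_mean=mean, slope_sd=sd,
        relative_deviation_pct=float(rel_dev), mean_reported_se=mean_se,
        se_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# relative L2 validation

def relative_l2_norm(predicted, observed) -> float:
    """||predicted - observed||_2 / ||observed||_2 (0 iff perfect)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("predicted and observed must be equal-length 1-d vectors")
    denom = float(np.sqrt((obs ** 2).sum()))
    if denom == 0:
        raise ZeroDivisionError("observed vector is all zero; relative norm undefined")
    return float(np.sqrt(((pred - obs) ** 2).sum()) / denom)


@dataclass
class ValidationResult:
    model: str
    ions: tuple
    predicted: tuple
    observed: tuple
    norm: float
    excluded: tuple = ()


def validate_on_new_ions(fit: RobustFit, props: PropertyTable,
                         scores: DiseaseScoreSet, ions) -> ValidationResult:
    """Relative L2 misfit of *fit* on held-out ions.

    The fit must carry its endpoint and property metadata (set by the
    screen).  Ions lacking either the descriptor value or an observed score
    are excluded with a warning entry; if none remain, raise.
    """
    ions = list(ions)
    if not ions:
        raise ValueError("no held-out ions given")
    if fit.property is None or fit.endpoint is None:
        raise ValueError("fit lacks endpoint/property metadata needed for validation")
    used, excluded, preds, obs = [], [], [], []
    for ion in ions:
        try:
            xval = float(props.values_of(fit.property, [ion]).loc[ion])
            yval = float(np.log(scores.score(fit.endpoint, ion)))
        except (KeyError, ValueError):
            excluded.append(ion)
            continue
        used.append(ion)
        preds.append(fit.intercept + fit.slope * xval)
        obs.append(yval)
    if not used:
        raise ValueError(f"none of {ions} has both a descriptor value and a score")
    norm = relative_l2_norm(preds, obs)
    label = f"{fit.endpoint}/{fit.group}/{fit.property}"
    return ValidationResult(model=label, ions=tuple(used), predicted=tuple(preds),
                            observed=tuple(obs), norm=norm, excluded=tuple(excluded))


# ---------------------------------------------------------------------------
# estimator comparison

@dataclass
class EstimatorComparison:
    """Slopes of the four robust families on one cell, with agreement flags."""

    slopes: dict = field(default_factory=dict)          # method -> slope
    failures: dict = field(default_factory=dict)        # method -> error text
    pairwise_rel_diff: dict = field(default_factory=dict)  # (m1, m2) -> rel diff

    @property
    def partial(self) -> bool:
        return bool(self.failures)

    def agree_within(self, tol: float) -> bool:
        """True when every pairwise relative slope difference is <= tol.

        tol=0 tests exact equivalence (to numerical noise, 1e-10); tol=0.2
        is the 20%-agreement flag.
        """
        if self.partial or not self.pairwise_rel_diff:
            return False
        cut = 1e-10 if tol == 0 else tol
        return all(d <= cut for d in self.pairwise_rel_diff.values())


def compare_estimators(x, y, h: int | None = None) -> EstimatorComparison:
    """Fit LTS, M, S and MM on (x, y) and tabulate slope disagreement.

    Relative difference for a pair is |s1 - s2| / max(|s1|, |s2|) (symmetric;
    0 when both slopes are zero).  A method that fails leaves the comparison
    marked partial rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if h is None:
        h, _ = trim_count(x.size)
    comp = EstimatorComparison()
    for method in ESTIMATORS:
        try:
            if method == "LTS":
                fit = lts_fit(x, y, h)
            else:
                fit = robust_fit(x, y, method)
            comp.slopes[method] = fit.slope
        except (ValueError, ZeroDivisionError) as exc:
            comp.failures[method] = str(exc)
        except ConvergenceError as exc:
            comp.failures[method] = str(exc)
    methods = sorted(comp.slopes)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            s1, s2 = comp.slopes[m1], comp.slopes[m2]
            scale = max(abs(s1), abs(s2))
            diff = 0.0 if scale == 0 else abs(s1 - s2) / scale
            comp.pairwise_rel_diff[(m1, m2)] = diff
            comp.pairwise_rel_diff[(m2, m1)] = diff
    return comp
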