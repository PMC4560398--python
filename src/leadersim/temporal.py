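"""Temporal curves over generations: smoothing, derivatives, event order,
correlations and leadership-style classification.

The evolutionary dynamics of leadership are read off curves sampled
every 10 generations: the four per-robot barycenter curves, the four
individual-fitness curves, and the collective-fitness curve.  Curves
are smoothed with Friedman's variable-span super-smoother before
differentiation; only the *locations* of derivative maxima are consumed
downstream (e.g. "does the leader's skill peak before its leadership
status?"), which makes the analysis robust to the units of the
derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evolution import EvolvedTeam, ReplicationResult
from .measures import (barycenter_quadruple, individual_fitness_quadruple)
from .world import ArenaConfig, N_ROBOTS

STYLE_LABELS = ("passive", "weak_active", "strong_active")


@dataclass
class TemporalCurve:
    """Values sampled on a strictly increasing generation grid."""

    generations: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.generations.shape != self.values.shape:
            raise ValueError("generations and values must have equal length")
        if self.generations.size > 1 and np.any(np.diff(self.generations) <= 0):
            raise ValueError("generation samples must be strictly increasing")

    def __len__(self) -> int:
        return self.generations.size

    def with_values(self, values: np.ndarray) -> "TemporalCurve":
        return TemporalCurve(self.generations.copy(), values)


# ---------------------------------------------------------------------------
# Friedman's super-smoother

_SPANS = (0.05, 0.2, 0.5)  # tweeter, midrange, woofer
_MIDRANGE = 0.2


def _running_linear(x, y, span):
    """Running local-linear smooth plus leave-one-out CV residuals.

    The window for point i is the ``J`` nearest points in rank order
    (symmetric where possible).  The CV residual refits the window with
    point i excluded (exact leave-one-out, well defined for any J).
    Returns (fit, |cv residual|).
    """

    def line_fit(xw, yw, x0):
        xbar = xw.mean()
        sxx = np.sum((xw - xbar) ** 2)
        ybar = yw.mean()
        if sxx <= 0:
            return ybar
        b = np.sum((xw - xbar) * (yw - ybar)) / sxx
        return ybar + b * (x0 - xbar)

    n = x.size
    J = max(2, int(round(span * n)))
    J = min(J, n)
    half = J // 2
    fit = np.empty(n)
    cv = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - J))
        w = np.arange(lo, lo + J)
        fit[i] = line_fit(x[w], y[w], x[i])
        w_loo = w[w != i]
        cv[i] = abs(y[i] - line_fit(x[w_loo], y[w_loo], x[i]))
    return fit, cv


def supersmoother(x: np.ndarray, y: np.ndarray,
                  bass: float = 0.0) -> np.ndarray:
    """Friedman's variable-span running-linear smoother.

    Three fixed spans (0.05, 0.2, 0.5 of the data) are fitted by local
    linear regression; the best span at each point is chosen by
    smoothed leave-one-out cross-validated absolute residuals, optionally
    biased toward larger spans by ``bass`` in [0, 10]; the chosen spans
    are themselves smoothed and the final value interpolates between the
    two bracketing fixed-span fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        return y.copy()
    fits = np.empty((len(_SPANS), n))
    resids = np.empty((len(_SPANS), n))
    for k, span in enumerate(_SPANS):
        fits[k], resids[k] = _running_linear(x, y, span)
    # smooth the CV residuals with the midrange span before comparing
    sm_resid = np.empty_like(resids)
    for k in range(len(_SPANS)):
        sm_resid[k], _ = _running_linear(x, resids[k], _MIDRANGE)
    best = np.argmin(sm_resid, axis=0)
    span_sel = np.array([_SPANS[k] for k in best])
    if bass > 0.0:
        # bass enhancement: pull the selected spans toward the woofer
        rmin = sm_resid[best, np.arange(n)]
        rwoof = sm_resid[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rwoof > 0, rmin / rwoof, 1.0)
        alpha = bass / 10.0
        span_sel = span_sel + (_SPANS[-1] - span_sel) * ratio ** (10.0 - bass) * alpha
    span_smooth, _ = _running_linear(x, span_sel, _MIDRANGE)
    span_smooth = np.clip(span_smooth, _SPANS[0], _SPANS[-1])
    # interpolate between the two fixed-span fits bracketing each chosen span
    out = np.empty(n)
    spans = np.array(_SPANS)
    for i in range(n):
        s = span_smooth[i]
        k = int(np.searchsorted(spans, s))
        if k == 0:
            out[i] = fits[0, i]
        elif k >= len(spans):
            out[i] = fits[-1, i]
        else:
            f = (s - spans[k - 1]) / (spans[k] - spans[k - 1])
            out[i] = (1 - f) * fits[k - 1, i] + f * fits[k, i]
    return out


def smooth(curve: TemporalCurve, bass: float = 0.0) -> TemporalCurve:
    """Super-smooth a temporal curve on its own sample grid."""
    if len(curve) < 10:
        raise ValueError("smoothing needs at least 10 samples")
    return curve.with_values(supersmoother(curve.generations, curve.values,
                                           bass=bass))


def derivative(curve: TemporalCurve) -> TemporalCurve:
    """Finite-difference derivative w.r.t. generations.

    Central differences in the interior, one-sided at the ends
    (``np.gradient`` with the generation abscissae).
    """
    if len(curve) < 2:
        raise ValueError("derivative needs at least 2 samples")
    return curve.with_values(np.gradient(curve.values, curve.generations))


# ---------------------------------------------------------------------------
# curve extraction from a replication


@dataclass
class TemporalCurves:
    """The full curve bundle of one replication."""

    barycenter: list        # 4 TemporalCurve, one per robot
    individual_fitness: list  # 4 TemporalCurve
    collective_fitness: TemporalCurve


def temporal_curves(replication: ReplicationResult, config: ArenaConfig,
                    rng: np.random.Generator, sample_step: int = 10,
                    n_trials: int = 20,
                    steps: int | None = None) -> TemporalCurves:
    """Re-run the measure protocols at every ``sample_step`` generations.

    Single-generation versions of the barycenter and individual-fitness
    protocols (that generation's best team, ``n_trials`` trials each);
    the collective curve reads the stored per-generation group fitness.
    """
    G = replication.n_generations
    gens = list(range(0, G, sample_step))
    if gens[-1] != G - 1:
        gens.append(G - 1)
    bary = np.zeros((len(gens), N_ROBOTS))
    indiv = np.zeros((len(gens), N_ROBOTS))
    for gi, g in enumerate(gens):
        team = EvolvedTeam(replication.best_team(g), config, label=f"gen{g}")
        bary[gi] = barycenter_quadruple(team, config, rng, n_trials,
                                        steps=steps)
        indiv[gi] = individual_fitness_quadruple(team, config, rng, n_trials,
                                                 steps=steps)
    gen_arr = np.asarray(gens, dtype=float)
    return TemporalCurves(
        barycenter=[TemporalCurve(gen_arr, bary[:, i]) for i in range(N_ROBOTS)],
        individual_fitness=[TemporalCurve(gen_arr, indiv[:, i])
                            for i in range(N_ROBOTS)],
        collective_fitness=TemporalCurve(
            gen_arr, replication.group_best[gens]),
    )


def distance_among_barycenter_curves(curves: list) -> TemporalCurve:
    """Mean absolute gap over the 6 unordered pairs of the 4 curves."""
    if len(curves) != N_ROBOTS:
        raise ValueError("four barycenter curves required")
    g0 = curves[0].generations
    for c in curves[1:]:
        if not np.array_equal(c.generations, g0):
            raise ValueError("curves must share the same sample grid")
    vals = np.stack([c.values for c in curves])
    gaps = [np.abs(vals[i] - vals[j])
            for i in range(N_ROBOTS) for j in range(i + 1, N_ROBOTS)]
    return TemporalCurve(g0.copy(), np.mean(gaps, axis=0))


def event_order(fitness_curve: TemporalCurve,
                barycenter_curve: TemporalCurve,
                bass: float = 0.0) -> bool:
    """Does the leader's skill peak before its leadership status?

    True iff the argmax generation of the smoothed individual-fitness
    derivative comes strictly before the argmax of the smoothed
    *inverted* barycenter derivative (the barycenter trend decreases as
    leadership consolidates, so it is negated before differentiation).
    Ties return False.
    """
    df = derivative(smooth(fitness_curve, bass=bass))
    inv = barycenter_curve.with_values(-barycenter_curve.values)
    db = derivative(smooth(inv, bass=bass))
    g_fit = df.generations[int(np.argmax(df.values))]
    g_bary = db.generations[int(np.argmax(db.values))]
    return bool(g_fit < g_bary)


# ---------------------------------------------------------------------------
# correlations and style classification


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


@dataclass
class StyleClassification:
    labels: list                    # one of STYLE_LABELS per replication
    thresholds: tuple | None        # (t1, t2) vision breakpoints, or None
    degenerate: bool = False


def classify_style(vision, mobility=None,
                   thresholds: tuple | None = None) -> StyleClassification:
    """Largest-gap three-way split of the sorted vision values.

    Replications sort ascending by the leader's vision activation; the
    two largest consecutive gaps define the breakpoints; the lowest
    group is labelled passive, the middle weak_active, the highest
    strong_active.  This is a declared heuristic analogue of assignment
    by behavioural inspection; pass manual ``thresholds`` (t1, t2) to
    override it.  All-equal input is degenerate: a single class,
    flagged.
    """
    vision = np.asarray(vision, dtype=float)
    n = vision.size
    if n < len(STYLE_LABELS) and thresholds is None:
        raise ValueError("need at least 3 replications to form 3 classes")
    if thresholds is not None:
        t1, t2 = sorted(thresholds)
        labels = [STYLE_LABELS[0] if v < t1 else
                  STYLE_LABELS[1] if v < t2 else STYLE_LABELS[2]
                  for v in vision]
        return StyleClassification(labels, (t1, t2))
    order = np.argsort(vision, kind="stable")
    sv = vision[order]
    gaps = np.diff(sv)
    if np.all(gaps == 0):
        return StyleClassification([STYLE_LABELS[0]] * n, None, degenerate=True)
    top = [int(k) for k in np.argsort(-gaps, kind="stable") if gaps[k] > 0][:2]
    cuts = np.sort(top)
    labels_sorted = np.empty(n, dtype=object)
    labels_sorted[: cuts[0] + 1] = STYLE_LABELS[0]
    if len(cuts) > 1:
        labels_sorted[cuts[0] + 1: cuts[1] + 1] = STYLE_LABELS[1]
        labels_sorted[cuts[1] + 1:] = STYLE_LABELS[2]
    else:
        labels_sorted[cuts[0] + 1:] = STYLE_LABELS[2]
    labels = np.empty(n, dtype=object)
    labels[order] = labels_sorted
    t1 = (sv[cuts[0]] + sv[cuts[0] + 1]) / 2.0
    t2 = (sv[cuts[1]] + sv[cuts[1] + 1]) / 2.0 if len(cuts) > 1 else t1
    return StyleClassification(list(labels), (float(t1), float(t2)))
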