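"""Mixed-model fits, Wald statistics, and cluster-permutation correction.

Per analysis unit (channel, voxel, or epoch) a linear mixed model
relates the response (e.g. a 1-5 sleepiness rating) to one EEG
feature, with random intercepts for subject and for time-of-night bin;
the Wald statistic is the squared ratio of the fixed-effect estimate
to its standard error.  Family-wise correction: connected clusters of
units with p < alpha are scored by sum(Wald)/cluster size; the null
distribution is built by shuffling the response within subjects
(n_perm times, refitting every unit per permutation) and keeping only
the maximum cluster statistic of each permutation; observed clusters
are significant above the empirical 95th percentile of that null.

Two fitters implement the per-unit model:

* ``mixedlm`` — statsmodels ``MixedLM`` with crossed variance
  components (subject, time-of-night bin); the reference
  implementation used by :func:`fit_unit_lmm`.
* ``fast`` — an exact GLS with the subject variance ratio profiled by
  REML on the intercept-only model and time-of-night bins absorbed as
  fixed dummies; refitting every unit for every permutation is then
  vectorized and cheap.  This is the permutation engine's default; the
  two agree closely on the Wald screen (see the test suite) and the
  permutation layer, not the asymptotics, carries the final inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as ss


@dataclass
class UnitModelResult:
    unit_id: str
    estimate: float
    se: float
    wald: float
    p: float | None
    converged: bool = True


@dataclass
class ClusterTestResult:
    clusters: list                 # (unit index array, cluster_stat, significant)
    null_distribution: np.ndarray  # per-permutation max cluster stat
    threshold: float               # empirical 95th percentile of the null
    n_perm: int
    seed: int
    stat_values: np.ndarray        # per-unit Wald (or t²) statistics
    pvals: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.stat_values.size, dtype=bool)
        for units, _, sig in self.clusters:
            if sig:
                m[units] = True
        return m

    @property
    def any_significant(self) -> bool:
        return any(sig for _, _, sig in self.clusters)


def _fit_mixedlm(model, reml: bool):
    """Fit a MixedLM, falling back across optimizers on numerical failure."""
    last = None
    for method in ("bfgs", "powell", "nm"):
        try:
            return model.fit(reml=reml, method=method)
        except Exception as e:     # singular Hessians, line-search failures
            last = e
    raise last


def tod_bins(time_of_night: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Bin time of night (hours) into thirds of the observed range."""
    t = np.asarray(time_of_night, dtype=float)
    edges = np.quantile(t, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    return np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)


# --------------------------------------------------------------------------
# per-unit mixed model (reference fitter)
# --------------------------------------------------------------------------

def fit_unit_lmm(response: np.ndarray, predictor: np.ndarray,
                 subject: np.ndarray, time_of_night: np.ndarray | None = None,
                 unit_id: str = "unit") -> UnitModelResult:
    """Mixed model of the response on one EEG feature.

    Random intercepts for subject and (when given) time-of-night bin;
    fixed slope for the predictor.  Non-convergence is flagged rather
    than raised; flagged units carry no p-value.
    """
    import statsmodels.formula.api as smf

    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    subject = np.asarray(subject)
    if np.unique(subject).size < 2:
        raise ValueError("need at least 2 subjects")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    df = pd.DataFrame({"y": y, "x": x, "subject": subject})
    vc = {"subject": "0 + C(subject)"}
    if time_of_night is not None:
        df["tod"] = tod_bins(np.asarray(time_of_night))
        if df["tod"].nunique() > 1:
            vc["tod"] = "0 + C(tod)"
    df["one"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm("y ~ x", groups="one", vc_formula=vc, data=df)
            fit = _fit_mixedlm(md, reml=True)
            est, se = float(fit.params["x"]), float(fit.bse["x"])
            wald = (est / se) ** 2
            return UnitModelResult(unit_id, est, se, wald,
                                   float(ss.chi2.sf(wald, 1)),
                                   converged=bool(fit.converged))
        except Exception:
            return UnitModelResult(unit_id, np.nan, np.nan, np.nan, None,
                                   converged=False)


# --------------------------------------------------------------------------
# fast exact-GLS fitter (vectorized across units)
# --------------------------------------------------------------------------

def _profile_gamma(y: np.ndarray, gidx: np.ndarray, n_groups: int) -> float:
    """REML variance ratio sigma_u^2/sigma_e^2 of the intercept-only model."""
    n = y.size
    counts = np.bincount(gidx, minlength=n_groups).astype(float)
    sums = np.bincount(gidx, weights=y, minlength=n_groups)
    yy = float(y @ y)

    def crit(log_g: float) -> float:
        g = np.exp(log_g)
        denom = 1.0 + g * counts
        s1 = float((counts / denom).sum())
        xy = float((sums / denom).sum())
        q = yy - g * float((sums**2 / denom).sum()) - xy**2 / s1
        q = max(q, 1e-12)
        return (n - 1) * np.log(q) + float(np.log(denom).sum()) + np.log(s1)

    res = optimize.minimize_scalar(crit, bounds=(-10.0, 6.0), method="bounded")
    return float(np.exp(res.x))


def _gls_walds(y: np.ndarray, x_units: np.ndarray, gidx: np.ndarray,
               n_groups: int, z_extra: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit slope, SE, Wald, p for y ~ x_u with a subject random
    intercept (gamma profiled on the intercept model), vectorized."""
    n, n_units = x_units.shape
    gamma = _profile_gamma(y, gidx, n_groups)
    counts = np.bincount(gidx, minlength=n_groups).astype(float)
    lam = 1.0 - 1.0 / np.sqrt(1.0 + gamma * counts)        # quasi-demeaning

    def transform(v: np.ndarray) -> np.ndarray:
        means = np.zeros((n_groups,) + v.shape[1:])
        np.add.at(means, gidx, v)
        means /= counts.reshape((-1,) + (1,) * (v.ndim - 1))
        return v - lam.reshape((-1,) + (1,) * (v.ndim - 1))[gidx] * means[gidx]

    ys = transform(y[:, None])[:, 0]
    xs = transform(x_units)
    cols = [transform(np.ones((n, 1)))[:, 0]]
    if z_extra is not None:
        cols.extend(transform(z_extra).T)
    z = np.column_stack(cols)
    # partial the common covariates out of y* and every x*
    q, _ = np.linalg.qr(z)
    ys = ys - q @ (q.T @ ys)
    xs = xs - q @ (q.T @ xs)
    sxx = (xs * xs).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    b = (xs * ys[:, None]).sum(axis=0) / sxx
    resid = ys[:, None] - b[None, :] * xs
    dof = n - z.shape[1] - 1
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 / sxx)
    wald = (b / se) ** 2
    return b, se, wald, ss.chi2.sf(wald, 1)


# --------------------------------------------------------------------------
# clustering machinery
# --------------------------------------------------------------------------

def _components(units: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the selected units in the adjacency graph."""
    unset = set(units.tolist())
    comps = []
    while unset:
        stack = [unset.pop()]
        comp = {stack[0]}
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adjacency[u]):
                if v in unset:
                    unset.discard(int(v))
                    comp.add(int(v))
                    stack.append(int(v))
        comps.append(np.array(sorted(comp)))
    return comps


def _chain_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = True
    return adj


def _cluster_stats(stats_per_unit: np.ndarray, pvals: np.ndarray,
                   adjacency: np.ndarray, alpha: float):
    sig = np.flatnonzero(pvals < alpha)
    comps = _components(sig, adjacency) if sig.size else []
    return [(c, float(stats_per_unit[c].sum() / c.size)) for c in comps]


def _max_cluster_stat(stats_per_unit, pvals, adjacency, alpha) -> float:
    cs = _cluster_stats(stats_per_unit, pvals, adjacency, alpha)
    return max((abs(s) for _, s in cs), default=0.0)


def _shuffle_within(rng: np.random.Generator, y: np.ndarray,
                    gidx: np.ndarray, n_groups: int) -> np.ndarray:
    out = y.copy()
    for g in range(n_groups):
        sel = np.flatnonzero(gidx == g)
        out[sel] = y[sel[rng.permutation(sel.size)]]
    return out


def cluster_permutation(response: np.ndarray, predictors: np.ndarray,
                        subject: np.ndarray, adjacency: np.ndarray,
                        time_of_night: np.ndarray | None = None,
                        n_perm: int = 1000, alpha: float = 0.05,
                        seed: int = 0) -> ClusterTestResult:
    """Within-subject cluster-permutation test of per-unit mixed models.

    ``predictors`` is observations x units.  The response is shuffled
    within subjects ``n_perm`` times; every unit is refit per
    permutation (fast GLS fitter); each permutation contributes its
    maximum absolute cluster statistic to the null.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for a 95th-percentile threshold")
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictors, dtype=float)
    if adjacency.shape[0] != x.shape[1]:
        raise ValueError("adjacency must cover all units")
    subj_codes, gidx = np.unique(subject, return_inverse=True)
    n_groups = subj_codes.size
    z = None
    if time_of_night is not None:
        bins = tod_bins(np.asarray(time_of_night))
        if np.unique(bins).size > 1:
            z = pd.get_dummies(bins, drop_first=True).to_numpy(dtype=float)

    _, _, wald, pv = _gls_walds(y, x, gidx, n_groups, z)
    observed = _cluster_stats(wald, pv, adjacency, alpha)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = _shuffle_within(rng, y, gidx, n_groups)
        _, _, w_p, p_p = _gls_walds(yp, x, gidx, n_groups, z)
        null[i] = _max_cluster_stat(w_p, p_p, adjacency, alpha)
    threshold = float(np.percentile(null, 95))
    clusters = [(c, s, bool(s > threshold)) for c, s in observed]
    return ClusterTestResult(clusters=clusters, null_distribution=null,
                             threshold=threshold, n_perm=n_perm, seed=seed,
                             stat_values=wald, pvals=pv)


def _paired_t(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise one-sample t on subject x unit differences."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t = np.where(np.isfinite(t), t, 0.0)
    return t, 2.0 * ss.t.sf(np.abs(t), n - 1)


def _signflip_cluster(diff: np.ndarray, adjacency: np.ndarray, alpha: float,
                      n_perm: int, seed: int) -> ClusterTestResult:
    t, pv = _paired_t(diff)
    observed = _cluster_stats(t**2, pv, adjacency, alpha)
    rng = np.random.default_rng(seed)
    n_subj = diff.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        tp, pp = _paired_t(diff * flips[:, None])
        null[i] = _max_cluster_stat(tp**2, pp, adjacency, alpha)
    threshold = float(np.percentile(null, 95))
    clusters = [(c, s, bool(s > threshold)) for c, s in observed]
    return ClusterTestResult(clusters=clusters, null_distribution=null,
                             threshold=threshold, n_perm=n_perm, seed=seed,
                             stat_values=t, pvals=pv)


def timecourse_cluster_correct(diffs: np.ndarray, alpha: float = 0.05,
                               n_perm: int = 1000, seed: int = 0) -> ClusterTestResult:
    """Cluster correction over contiguous epochs of paired differences
    (subjects x epochs), with sign-flip permutations of subjects."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2:
        raise ValueError("expected subjects x epochs differences")
    return _signflip_cluster(diffs, _chain_adjacency(diffs.shape[1]),
                             alpha, n_perm, seed)


def paired_cluster_test(a: np.ndarray, b: np.ndarray, adjacency: np.ndarray,
                        alpha: float = 0.05, n_perm: int = 1000,
                        seed: int = 0) -> ClusterTestResult:
    """Paired comparison of subject x unit matrices over a unit adjacency.

    NaN subject/unit cells (e.g. empty slow-wave windows) are treated
    pairwise: the difference is NaN-masked per unit before testing.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.where(np.isfinite(d), d, 0.0)
    return _signflip_cluster(d, adjacency, alpha, n_perm, seed)


# --------------------------------------------------------------------------
# stage effects on sleepiness
# --------------------------------------------------------------------------

@dataclass
class StageContrastResult:
    chi2: float
    df: int
    p: float
    stage_means: dict
    pairwise: dict                 # (stage_a, stage_b) -> (estimate, z, p_holm)


def stage_contrasts(sleepiness: np.ndarray, stage: np.ndarray,
                    subject: np.ndarray, time_of_night: np.ndarray | None = None,
                    correct_time: bool = False) -> StageContrastResult:
    """Mixed-model stage effect on sleepiness with pairwise contrasts.

    Likelihood-ratio test of the stage factor (subject random
    intercept; optional time-of-night covariate), then Holm-corrected
    pairwise stage contrasts from the full fit.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    stages = sorted(set(stage))
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    df = pd.DataFrame({"y": np.asarray(sleepiness, dtype=float),
                       "stage": stage, "subject": subject})
    rhs_extra = ""
    if correct_time:
        if time_of_night is None:
            raise ValueError("correct_time requires time_of_night")
        df["tod"] = np.asarray(time_of_night, dtype=float)
        rhs_extra = " + tod"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = _fit_mixedlm(smf.mixedlm("y ~ C(stage)" + rhs_extra,
                                        groups="subject", data=df), reml=False)
        null = _fit_mixedlm(smf.mixedlm("y ~ 1" + rhs_extra,
                                        groups="subject", data=df), reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    dof = len(stages) - 1
    p = float(ss.chi2.sf(chi2, dof))

    means = {}
    base = stages[0]
    coef = {base: 0.0}
    for s in stages[1:]:
        coef[s] = float(full.params[f"C(stage)[T.{s}]"])
    intercept = float(full.params["Intercept"])
    for s in stages:
        means[s] = intercept + coef[s]

    pairs, zs, ps_raw, ests = [], [], [], []
    cov = full.cov_params()
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            a, b = stages[i], stages[j]
            est = coef[a] - coef[b]
            name_a = f"C(stage)[T.{a}]" if a != base else None
            name_b = f"C(stage)[T.{b}]" if b != base else None
            var = 0.0
            if name_a:
                var += cov.loc[name_a, name_a]
            if name_b:
                var += cov.loc[name_b, name_b]
            if name_a and name_b:
                var -= 2 * cov.loc[name_a, name_b]
            se = np.sqrt(max(var, 1e-12))
            z = est / se
            pairs.append((a, b))
            ests.append(est)
            zs.append(z)
            ps_raw.append(2 * ss.norm.sf(abs(z)))
    if pairs:
        _, p_holm, _, _ = multipletests(ps_raw, method="holm")
    pairwise = {pr: (ests[k], zs[k], float(p_holm[k])) for k, pr in enumerate(pairs)}
    return StageContrastResult(chi2=float(chi2), df=dof, p=p,
                               stage_means=means, pairwise=pairwise)
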