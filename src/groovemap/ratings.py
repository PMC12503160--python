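"""Rating-level analyses: similarity matrices, mixed models, and post-hocs.

The two groove components (wanting to move, pleasure) are modeled
separately.  ``fit_genre_model`` estimates genre effects on ratings with
funk as the treatment reference and familiarity plus formal/informal musical
training as covariates, under crossed random effects (by-participant and
by-stimulus).  ``fit_entropy_model`` regresses ratings on orthogonal linear
and quadratic terms of pulse entropy (the inverted-U analysis).  Nested
fits are compared with a likelihood-ratio chi-square, and pairwise genre
contrasts are adjusted with the multivariate-t method.

Backend notes
-------------
Models are fit with statsmodels ``MixedLM``; the crossed random effects are
encoded as variance components on a single grouping blob (the standard
statsmodels idiom).  Random genre slopes are encoded as participant-by-genre
(or stimulus-by-genre) variance components, i.e. a compound-symmetry slope
structure.  Singular or non-converging fits descend a documented fallback
ladder (drop stimulus slopes, then participant slopes, then keep intercepts
only); the structure that converged is recorded on the returned fit.
Denominator degrees of freedom use a classical between-within assignment
(stimulus-level effects such as genre: n_stimuli minus the stimulus-level
parameter count; participant-level covariates analogously; observation-level
covariates: residual df), labeled ``between-within`` in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelFit",
    "similarity_matrix",
    "fit_genre_model",
    "fit_null_model",
    "fit_entropy_model",
    "compare_models",
    "posthoc_pairwise",
]

GENRES = ("funk", "jazz_funk", "rock")

#: Fallback ladder for the genre model's random-effects structure, fullest
#: first.  Each entry lists the variance components included in the fit.
_LADDER = (
    ("participant", "participant_x_genre", "stimulus", "stimulus_x_genre"),
    ("participant", "participant_x_genre", "stimulus"),
    ("participant", "stimulus"),
)

_VC_FORMULAS = {
    "participant": "0 + C(participant_id)",
    "participant_x_genre": "0 + C(participant_id):C(genre)",
    "stimulus": "0 + C(stimulus_id)",
    "stimulus_x_genre": "0 + C(stimulus_id):C(genre)",
}


@dataclass
class ModelFit:
    """Coefficient table and metadata of one mixed-model fit."""

    fixed_estimates: dict  # name -> {estimate, se, df, t, p}
    variance_components: dict  # name -> sd
    log_likelihood: float
    converged: bool
    formula_label: str
    method: str  # "REML" or "ML"
    structure: tuple  # variance components retained by the fallback ladder
    ladder_log: list = field(default_factory=list)
    df_method: str = "between-within"
    n_obs: int = 0
    n_fixed: int = 0
    basis: dict = field(default_factory=dict)  # polynomial basis record
    cov_fixed: pd.DataFrame | None = None

    def coef(self, name: str) -> dict:
        return self.fixed_estimates[name]

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald CI using the coefficient's between-within t reference."""
        c = self.fixed_estimates[name]
        crit = stats.t.ppf(0.5 + level / 2.0, c["df"])
        return c["estimate"] - crit * c["se"], c["estimate"] + crit * c["se"]


def _check_complete(table: pd.DataFrame, component: str) -> pd.DataFrame:
    sub = table[table["component"] == component]
    if sub.empty:
        raise ValueError(f"no rows for component {component!r}")
    counts = sub.groupby(["participant_id", "stimulus_id"]).size()
    n_p = sub["participant_id"].nunique()
    n_s = sub["stimulus_id"].nunique()
    if len(counts) != n_p * n_s or (counts != 1).any():
        missing = [
            (p, s)
            for p in sub["participant_id"].unique()
            for s in sub["stimulus_id"].unique()
            if (p, s) not in counts.index
        ]
        raise ValueError(
            f"incomplete participant x stimulus crossing for {component!r}; "
            f"missing cells (first 5): {missing[:5]}"
        )
    return sub


def similarity_matrix(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Stimulus-by-stimulus Euclidean distance between participant-rating vectors.

    Each stimulus is represented by its vector of per-participant ratings for
    the given component; entry (i, j) is the Euclidean distance between the
    two vectors (0 = identically rated).  Requires a complete participant x
    stimulus crossing; missing cells raise rather than being imputed.
    """
    sub = _check_complete(table, component)
    wide = sub.pivot(index="participant_id", columns="stimulus_id", values="rating")
    d = squareform(pdist(wide.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=wide.columns, columns=wide.columns)


def _bw_df(
    term: str, n_obs: int, n_fixed: int, n_participants: int, n_stimuli: int
) -> float:
    """Between-within denominator df assignment for a fixed-effect term."""
    if "genre" in term or "entropy" in term:
        # varies between stimuli only: stimulus-level strata
        n_stim_params = 3 if "genre" in term else 3  # intercept + 2 terms
        return float(max(n_stimuli - n_stim_params, 1))
    if "training" in term:
        return float(max(n_participants - 3, 1))
    return float(max(n_obs - n_fixed - (n_participants - 1) - (n_stimuli - 1), 1))


def _fit_mixed(
    data: pd.DataFrame,
    fixed_formula: str,
    vc_names: tuple,
    reml: bool,
    label: str,
    basis: dict | None = None,
) -> ModelFit:
    """Fit one MixedLM with the crossed-VC encoding and a fallback ladder."""
    data = data.copy()
    data["_one"] = 1
    ladder_log: list[str] = []

    # Degenerate zero-residual data (e.g. noise-free simulations): the mixed
    # likelihood is unbounded, but the fixed effects are the interpolating
    # least-squares solution; return that directly.
    ols = smf.ols(fixed_formula, data).fit()
    if ols.ssr / max(ols.nobs, 1) < 1e-12:
        ladder_log.append("zero-residual data: exact least-squares interpolation")
        n_p = data["participant_id"].nunique()
        n_s = data["stimulus_id"].nunique()
        fixed = {}
        for name in ols.params.index:
            est = float(ols.params[name])
            se = float(ols.bse[name])
            df = _bw_df(name, int(ols.nobs), len(ols.params), n_p, n_s)
            fixed[name] = {
                "estimate": est, "se": se, "df": df,
                "t": est / se if se > 0 else np.nan,
                "p": float(2 * stats.t.sf(abs(est / se), df)) if se > 0 else np.nan,
            }
        return ModelFit(
            fixed_estimates=fixed,
            variance_components={name: 0.0 for name in vc_names} | {"residual": 0.0},
            log_likelihood=float(ols.llf),
            converged=True,
            formula_label=label,
            method="REML" if reml else "ML",
            structure=(),
            ladder_log=ladder_log,
            n_obs=int(ols.nobs),
            n_fixed=len(ols.params),
            basis=basis or {},
            cov_fixed=pd.DataFrame(
                np.asarray(ols.cov_params()),
                index=list(ols.params.index), columns=list(ols.params.index),
            ),
        )
    ladder = [vc_names] + [
        lvl for lvl in _LADDER if len(lvl) < len(vc_names) and set(lvl) <= set(vc_names)
    ]
    if ("participant",) not in [tuple(l) for l in ladder]:
        ladder.append(("participant",))
    last_exc: Exception | None = None
    for structure in ladder:
        vcf = {name: _VC_FORMULAS[name] for name in structure}
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = sm.MixedLM.from_formula(
                    fixed_formula, data, groups="_one", vc_formula=vcf, re_formula="0"
                )
                # Gradient-based and derivative-free optimizers can land on
                # different optima of the profiled (RE)ML surface, especially
                # with variance components near the boundary; fit with both
                # and keep the higher likelihood.
                res = None
                for opt in ("lbfgs", "powell"):
                    cand = model.fit(reml=reml, method=opt, maxiter=500, disp=False)
                    if res is None or (
                        np.isfinite(cand.llf) and cand.llf > res.llf + 1e-8
                    ):
                        res = cand
            bad = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
            if not res.converged or (bad and not np.all(np.isfinite(res.bse_fe))):
                ladder_log.append(f"{structure}: non-convergence, descending")
                continue
            ladder_log.append(f"{structure}: converged")
            return _pack_fit(model, res, structure, reml, label, ladder_log, basis, data)
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            last_exc = exc
            ladder_log.append(f"{structure}: {exc!r}, descending")
    raise RuntimeError(f"no model on the fallback ladder converged: {ladder_log}") from last_exc


def _pack_fit(model, res, structure, reml, label, ladder_log, basis, data) -> ModelFit:
    n_obs = int(model.nobs)
    fe_names = list(model.exog_names)
    n_fixed = len(fe_names)
    n_p = data["participant_id"].nunique()
    n_s = data["stimulus_id"].nunique()
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:n_fixed, :n_fixed], index=fe_names, columns=fe_names
    )
    fixed = {}
    for i, name in enumerate(fe_names):
        est = float(res.fe_params.iloc[i])
        se = float(res.bse_fe.iloc[i])
        df = _bw_df(name, n_obs, n_fixed, n_p, n_s)
        t = est / se if se > 0 else np.nan
        fixed[name] = {
            "estimate": est,
            "se": se,
            "df": df,
            "t": t,
            "p": float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan,
        }
    vc = {}
    vcomp = np.asarray(res.vcomp, dtype=float)
    for name, v in zip(structure, vcomp):
        vc[name] = float(np.sqrt(max(v, 0.0)))
    vc["residual"] = float(np.sqrt(res.scale))
    return ModelFit(
        fixed_estimates=fixed,
        variance_components=vc,
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
        formula_label=label,
        method="REML" if reml else "ML",
        structure=tuple(structure),
        ladder_log=ladder_log,
        n_obs=n_obs,
        n_fixed=n_fixed,
        basis=basis or {},
        cov_fixed=cov,
    )


_GENRE_FIXED = (
    "rating ~ C(genre, Treatment('funk')) + familiarity"
    " + formal_training_years + informal_training_years"
)
_NULL_FIXED = "rating ~ familiarity + formal_training_years + informal_training_years"


def fit_genre_model(
    table: pd.DataFrame,
    component: str,
    reml: bool = True,
    random_structure: tuple = _LADDER[0],
) -> ModelFit:
    """Mixed model of ratings on genre with funk as the treatment reference.

    Fixed effects: genre (treatment contrasts funk vs jazz funk / rock),
    familiarity, formal and informal musical training.  Random effects start
    from ``random_structure`` (default: by-participant and by-stimulus
    intercepts and genre slopes) and descend the fallback ladder on
    non-convergence.  REML by default; fit with ``reml=False`` for
    likelihood-ratio comparisons.
    """
    sub = _check_complete(table, component)
    if sub["genre"].nunique() != 3 or "funk" not in set(sub["genre"]):
        raise ValueError("genre must have 3 levels with funk present as reference")
    return _fit_mixed(
        sub, _GENRE_FIXED, tuple(random_structure), reml,
        label=f"genre model [{component}]",
    )


def fit_null_model(table: pd.DataFrame, component: str, reml: bool = False,
                   random_structure: tuple = ("participant", "stimulus")) -> ModelFit:
    """Covariates-only reduction of the genre model (for LRT comparisons)."""
    sub = _check_complete(table, component)
    return _fit_mixed(
        sub, _NULL_FIXED, tuple(random_structure), reml,
        label=f"null model [{component}]",
    )


def compare_models(null_fit: ModelFit, full_fit: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both fits must be maximum-likelihood (not REML) on the same data.
    Returns (chi-square = 2 * delta logLik floored at 0, df = fixed-parameter
    difference, upper-tail chi-square p; p = 1 for identical models).
    """
    for f in (null_fit, full_fit):
        if f.method != "ML":
            raise ValueError("likelihood-ratio comparison requires ML fits (reml=False)")
    if null_fit.n_obs != full_fit.n_obs:
        raise ValueError("fits are not on the same data")
    df = full_fit.n_fixed - null_fit.n_fixed
    if df < 0 or not set(null_fit.fixed_estimates) <= set(full_fit.fixed_estimates):
        raise ValueError("models are not nested (null must be a reduction of full)")
    chi2 = max(0.0, 2.0 * (full_fit.log_likelihood - null_fit.log_likelihood))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def posthoc_pairwise(
    fit: ModelFit, factor: str = "genre", levels: tuple = GENRES, seed: int = 0
) -> pd.DataFrame:
    """All pairwise genre contrasts with multivariate-t familywise adjustment.

    Contrast estimates and SEs come from the fixed-effect covariance of the
    fitted model (treatment coding, first level = reference).  The adjusted p
    for each contrast is P(max_j |T_j| >= |t|) under a multivariate t over
    the whole contrast set with the contrasts' estimated correlation and the
    factor's between-within df; if that integration fails, a Tukey
    studentized-range adjustment is used and labeled.
    """
    fe = fit.fixed_estimates
    names = [n for n in fe if factor in n]
    if len(names) < 1:
        raise ValueError(f"fit has no {factor!r} terms")
    ref = levels[0]
    term_of = {}
    for lev in levels[1:]:
        match = [n for n in names if f"[T.{lev}]" in n]
        if not match:
            raise ValueError(f"no coefficient found for level {lev!r}")
        term_of[lev] = match[0]

    cov = fit.cov_fixed
    order = list(cov.columns)
    k = len(order)
    rows_c = []
    labels = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            c = np.zeros(k)
            # mean(la) - mean(lb) under treatment coding
            if la != ref:
                c[order.index(term_of[la])] += 1.0
            if lb != ref:
                c[order.index(term_of[lb])] -= 1.0
            rows_c.append(c)
            labels.append(f"{la} - {lb}")
    C = np.array(rows_c)
    beta = np.array([fe[n]["estimate"] if n in fe else 0.0 for n in order])
    est = C @ beta
    V = C @ cov.to_numpy() @ C.T
    se = np.sqrt(np.diag(V))
    tvals = est / se
    df = fe[next(iter(term_of.values()))]["df"]
    p_unadj = 2.0 * stats.t.sf(np.abs(tvals), df)

    R = V / np.outer(se, se)
    method = "multivariate-t"
    p_adj = np.empty_like(p_unadj)
    if len(labels) == 1:
        p_adj[:] = p_unadj
        method = "single-contrast (no adjustment)"
    else:
        try:
            mvt = stats.multivariate_t(loc=np.zeros(len(labels)), shape=R, df=df,
                                       allow_singular=True)
            rng = np.random.default_rng(seed)
            for i, t in enumerate(np.abs(tvals)):
                inside = mvt.cdf(
                    np.full(len(labels), t),
                    lower_limit=np.full(len(labels), -t),
                    random_state=rng,
                )
                p_adj[i] = min(1.0, max(0.0, 1.0 - inside))
        except Exception:  # pragma: no cover - numerical fallback
            crit = np.abs(tvals) * np.sqrt(2.0)
            p_adj = stats.studentized_range.sf(crit, len(levels), df)
            method = "tukey (studentized range fallback)"
    p_adj = np.maximum(p_adj, p_unadj)  # adjustment never helps a contrast

    return pd.DataFrame(
        {
            "contrast": labels,
            "estimate": est,
            "se": se,
            "df": df,
            "t": tvals,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "adjustment": method,
        }
    )


def _orthogonal_poly(x: np.ndarray, degree: int) -> tuple[np.ndarray, dict]:
    """Centered, scaled orthogonal polynomial basis (unit-variance columns).

    QR-orthogonalizes [1, z, z^2, ...] with z the standardized input, fixes
    column signs so the leading coefficient is positive (the quadratic column
    is then an increasing function of z^2), and scales each column to unit
    sample variance.  Returns (n x degree matrix, basis record).
    """
    z = np.asarray(x, dtype=float)
    sd = z.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(z).max())):
        raise ValueError("entropy is constant across stimuli; no identifiable slope")
    z = (z - z.mean()) / sd
    V = np.column_stack([z**d for d in range(degree + 1)])
    Q, Rm = np.linalg.qr(V)
    signs = np.sign(np.diag(Rm))
    signs[signs == 0] = 1.0
    Q = Q * signs
    cols = Q[:, 1:]
    scales = cols.std(axis=0)
    cols = cols / scales
    record = {
        "kind": "orthogonal polynomial (QR of standardized entropy, unit-variance columns)",
        "center": float(np.asarray(x, dtype=float).mean()),
        "scale": float(sd),
        "degree": degree,
    }
    return cols, record


def fit_entropy_model(
    table: pd.DataFrame,
    component: str,
    order: str = "quadratic",
    with_genre_interaction: bool = False,
    reml: bool = True,
) -> ModelFit:
    """Mixed model of ratings on orthogonal pulse-entropy polynomials.

    Pulse entropy is centered, scaled, and expanded into orthogonal linear
    (+ quadratic) columns; formal and informal musical training enter as
    covariates; random effects are by-participant and by-stimulus intercepts.
    A negative fitted quadratic term indicates the inverted-U relation
    between rhythm predictability and groove.  ``with_genre_interaction``
    adds entropy x genre terms.  The polynomial basis is recorded on the
    returned fit.
    """
    if order not in ("linear", "quadratic"):
        raise ValueError("order must be 'linear' or 'quadratic'")
    sub = _check_complete(table, component).copy()
    if sub["pulse_entropy"].isna().any():
        raise ValueError("pulse entropy missing for some stimuli")
    degree = 1 if order == "linear" else 2
    cols, record = _orthogonal_poly(sub["pulse_entropy"].to_numpy(), degree)
    sub["entropy_lin"] = cols[:, 0]
    terms = ["entropy_lin"]
    if degree == 2:
        sub["entropy_quad"] = cols[:, 1]
        terms.append("entropy_quad")
    if with_genre_interaction:
        terms += [f"{t}:C(genre, Treatment('funk'))" for t in terms]
    formula = (
        "rating ~ " + " + ".join(terms)
        + " + formal_training_years + informal_training_years"
    )
    return _fit_mixed(
        sub, formula, ("participant", "stimulus"), reml,
        label=f"entropy model [{component}, {order}]",
        basis=record,
    )
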