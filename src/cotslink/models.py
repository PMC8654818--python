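"""Hierarchical Bayesian regression core.

This module owns everything between a tidy data table and a posterior:
design construction for the three model families used in the analyses
(negative binomial counts, gamma positives, hurdle-gamma), weakly
informative priors, non-centred random intercepts, MCMC fitting with an
affine-invariant/differential-evolution ensemble sampler (emcee), and
posterior summarization into directional evidence classes.

Parameterization notes
----------------------
* All positive-scale parameters (gamma shape, NB dispersion, hierarchical
  SDs) are sampled on the log scale with the half-Normal prior applied on
  the natural scale plus the log Jacobian.
* Random intercepts are non-centred: ``effect = sigma * z`` with
  ``z ~ Normal(0, 1)``, which keeps the posterior geometry close to
  Gaussian and friendly to ensemble moves.
* The hurdle zero component models ``P(y == 0)`` on the logit scale; its
  fixed effects are separate from the gamma component, and random
  intercepts attach to the gamma (positive) component only, matching the
  analysis structure where the logistic part carries only zoning or
  coral-cover fixed effects.

Default priors (all overridable through :class:`PriorConfig`):
Student-t(3, 0, 2.5) intercepts, Normal(0, 2.5) slopes, half-Normal(0, 2)
hierarchical SDs, half-Normal(0, 5) shape/dispersion.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "HierarchicalModel",
    "PosteriorDraws",
    "EvidenceSummary",
    "ConvergenceWarning",
    "build_model",
    "fit",
    "summarize",
    "classify_evidence",
    "ppc_zero_fraction",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when split-R-hat or ESS thresholds fail."""


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the weakly informative default priors."""

    coef_scale: float = 2.5
    intercept_scale: float = 2.5
    intercept_df: float = 3.0
    sd_scale: float = 2.0
    aux_scale: float = 5.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    Parameters
    ----------
    family : {"negbin", "gamma", "hurdle_gamma"}
    response : str
        Column holding the response.
    terms : sequence of str
        Fixed-effect columns of the count/positive component (an
        intercept is always included first).
    zero_terms : sequence of str
        Fixed-effect columns of the hurdle zero component (hurdle only).
    groups : sequence of str
        Columns treated as random-intercept grouping factors on the
        count/positive component.
    centered : bool
        Sample random intercepts directly (centred parameterization)
        instead of as ``sigma * z`` with standard-normal ``z``.  Centred
        geometry mixes better when every group level is strongly
        informed by data (e.g. the reef-year intercepts).
    """

    family: Literal["negbin", "gamma", "hurdle_gamma"]
    response: str
    terms: tuple[str, ...] = ()
    zero_terms: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()
    centered: bool = False

    def __post_init__(self):
        if self.family not in ("negbin", "gamma", "hurdle_gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "hurdle_gamma" and self.zero_terms:
            raise ValueError("zero_terms only apply to the hurdle_gamma family")
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "zero_terms", tuple(self.zero_terms))
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class _RandomEffect:
    name: str
    codes: np.ndarray  # per positive/count row
    n_levels: int
    levels: list


def _design(data: pd.DataFrame, cols: Sequence[str], what: str) -> tuple[np.ndarray, list[str]]:
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"{what} column {c!r} not found in data")
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols]
    )
    for c in cols:
        col = data[c].to_numpy(dtype=float)
        if len(col) > 1 and np.ptp(col) == 0:
            warnings.warn(f"covariate {c!r} is constant in the data", UserWarning)
    return X, ["intercept"] + [f"b_{c}" for c in cols]


class HierarchicalModel:
    """A joint log-posterior over a flat named parameter vector.

    Built by :func:`build_model`; evaluates vectorized over walker
    matrices of shape ``(n_walkers, ndim)``.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, priors: PriorConfig | None = None):
        if len(data) == 0:
            raise ValueError("cannot build a model on an empty data table")
        self.spec = spec
        self.priors = priors or PriorConfig()
        self.include_likelihood = True

        if spec.response not in data.columns:
            raise KeyError(f"response column {spec.response!r} not found in data")
        y = data[spec.response].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError("response contains non-finite values")

        fam = spec.family
        if fam == "negbin":
            if np.any(y < 0) or np.any(y != np.floor(y)):
                raise ValueError("negbin response must be non-negative integers")
        elif fam == "gamma":
            if np.any(y <= 0):
                raise ValueError("gamma response must be strictly positive")
        else:
            if np.any(y < 0):
                raise ValueError("hurdle_gamma response must be non-negative")

        self.y = y
        self.is_zero = y == 0
        pos_rows = ~self.is_zero if fam == "hurdle_gamma" else np.ones(len(y), bool)
        self._pos_rows = pos_rows
        self.y_pos = y[pos_rows]

        # fixed-effect designs
        if fam == "hurdle_gamma":
            self.X_zero, self.zero_names = _design(data, spec.zero_terms, "zero-component")
            self.zero_names = [f"zero_{n}" for n in self.zero_names]
            Xp, pos_names = _design(data, spec.terms, "positive-component")
            self._full_pos_design = Xp
            self.X_pos = Xp[pos_rows]
        else:
            self.X_zero, self.zero_names = None, []
            self.X_pos, pos_names = _design(data, spec.terms, "fixed-effect")
            self._full_pos_design = self.X_pos
        self.pos_names = pos_names

        # random intercepts, levels taken over the full table
        self.random_effects: list[_RandomEffect] = []
        for g in spec.groups:
            if g not in data.columns:
                raise KeyError(f"grouping column {g!r} not found in data")
            cat = pd.Categorical(data[g])
            if len(cat.categories) < 1:
                raise ValueError(f"grouping factor {g!r} has no levels")
            codes = np.asarray(cat.codes, dtype=np.intp)[pos_rows]
            self.random_effects.append(
                _RandomEffect(g, codes, len(cat.categories), list(cat.categories))
            )

        self.aux_name = "dispersion" if fam == "negbin" else "shape"
        if fam == "negbin":
            # gammaln(y + phi) - gammaln(phi) vanishes at y == 0; counts are
            # zero-heavy, so restrict that term to the nonzero rows
            self._nz_idx = np.where(self.y_pos > 0)[0]
            self._y_nz = self.y_pos[self._nz_idx]
            self._gammaln_y1_sum = float(special.gammaln(self.y_pos + 1).sum())
        self._build_layout()

    # -- parameter layout --------------------------------------------------
    def _build_layout(self):
        names: list[str] = []
        slices: dict[str, slice] = {}
        i = 0

        def add(name, size):
            nonlocal i
            slices[name] = slice(i, i + size)
            names.extend([name] if size == 1 else [f"{name}[{k}]" for k in range(size)])
            i += size

        for n in self.zero_names:
            add(n, 1)
        for n in self.pos_names:
            add(n, 1)
        add(f"log_{self.aux_name}", 1)
        for re in self.random_effects:
            add(f"log_sigma_{re.name}", 1)
            add(f"z_{re.name}", re.n_levels)
        self.param_names = names
        self.slices = slices
        self.ndim = i

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def prior_only(self) -> "HierarchicalModel":
        """A copy whose posterior is the prior (likelihood switched off)."""
        m = copy.copy(self)
        m.include_likelihood = False
        return m

    # -- log densities -----------------------------------------------------
    def _coef_prior(self, x, name):
        p = self.priors
        if name.endswith("intercept"):
            s, df = p.intercept_scale, p.intercept_df
            return (
                special.gammaln((df + 1) / 2)
                - special.gammaln(df / 2)
                - 0.5 * math.log(df * math.pi * s * s)
                - (df + 1) / 2 * np.log1p(x * x / (df * s * s))
            )
        s = p.coef_scale
        return -0.5 * (x / s) ** 2 - math.log(s) - _LOG_SQRT_2PI

    @staticmethod
    def _log_halfnormal_on_exp(u, scale):
        # half-Normal(0, scale) density on exp(u), plus log-Jacobian u
        with np.errstate(over="ignore"):
            x2 = np.exp(2.0 * u)
        return (
            0.5 * math.log(2.0 / math.pi)
            - math.log(scale)
            - x2 / (2.0 * scale * scale)
            + u
        )

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        t2 = np.atleast_2d(theta)
        lp = np.zeros(t2.shape[0])
        for n in self.zero_names + self.pos_names:
            lp += self._coef_prior(t2[:, self.slices[n]].ravel(), n)
        lp += self._log_halfnormal_on_exp(
            t2[:, self.slices[f"log_{self.aux_name}"]].ravel(), self.priors.aux_scale
        )
        for re in self.random_effects:
            u_sd = t2[:, self.slices[f"log_sigma_{re.name}"]].ravel()
            lp += self._log_halfnormal_on_exp(u_sd, self.priors.sd_scale)
            z = t2[:, self.slices[f"z_{re.name}"]]
            if self.spec.centered:
                sd = np.exp(u_sd)[:, None]
                lp += np.sum(-0.5 * (z / sd) ** 2 - _LOG_SQRT_2PI, axis=1) \
                    - re.n_levels * u_sd
            else:
                lp += np.sum(-0.5 * z * z - _LOG_SQRT_2PI, axis=1)
        return lp if np.ndim(theta) == 2 else float(lp[0])

    def _linear_predictor(self, t2: np.ndarray) -> np.ndarray:
        """Positive/count-component eta, shape (n_walkers, n_component_rows)."""
        beta = np.column_stack([t2[:, self.slices[n]].ravel() for n in self.pos_names])
        eta = beta @ self.X_pos.T
        for re in self.random_effects:
            z = t2[:, self.slices[f"z_{re.name}"]]
            if self.spec.centered:
                eta = eta + z[:, re.codes]
            else:
                sd = np.exp(t2[:, self.slices[f"log_sigma_{re.name}"]])  # (nw, 1)
                eta = eta + sd * z[:, re.codes]
        return eta

    def log_likelihood_parts(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Component log-likelihoods; 'zero' is absent outside the hurdle family."""
        t2 = np.atleast_2d(np.asarray(theta, float))
        out: dict[str, np.ndarray] = {}
        with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
            if self.spec.family == "hurdle_gamma":
                gz = np.column_stack(
                    [t2[:, self.slices[n]].ravel() for n in self.zero_names]
                )
                eta_z = gz @ self.X_zero.T
                iz = self.is_zero
                ll = -(
                    iz * np.logaddexp(0.0, -eta_z) + (~iz) * np.logaddexp(0.0, eta_z)
                ).sum(axis=1)
                out["zero"] = ll

            eta = self._linear_predictor(t2)
            aux = np.exp(t2[:, self.slices[f"log_{self.aux_name}"]])  # (nw, 1)
            if self.spec.family == "negbin":
                y = self.y_pos
                mu = np.exp(eta)
                phi = aux[:, 0]  # (nw,)
                ll = (
                    special.gammaln(self._y_nz + aux).sum(axis=1)
                    - self._nz_idx.size * special.gammaln(phi)
                    - self._gammaln_y1_sum
                    + y.size * phi * np.log(phi)
                    - ((y + aux) * np.log(aux + mu)).sum(axis=1)
                    + (self._y_nz * eta[:, self._nz_idx]).sum(axis=1)
                )
                out["count"] = ll
            else:
                y = self.y_pos
                ll = (
                    aux * (np.log(aux) - eta)
                    - special.gammaln(aux)
                    + (aux - 1.0) * np.log(y)
                    - aux * y * np.exp(-eta)
                ).sum(axis=1)
                out["positive"] = ll
        return out

    def log_posterior(self, theta: np.ndarray) -> np.ndarray | float:
        t2 = np.atleast_2d(np.asarray(theta, float))
        lp = self.log_prior(t2)
        if self.include_likelihood:
            for ll in self.log_likelihood_parts(t2).values():
                lp = lp + ll
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp if np.ndim(theta) == 2 else float(lp[0])

    __call__ = log_posterior

    # -- initialization and simulation -------------------------------------
    def initial_points(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pts = rng.normal(0.0, 0.1, size=(n, self.ndim))
        if self.spec.family == "hurdle_gamma":
            zf = float(np.clip(self.is_zero.mean(), 0.02, 0.98))
            pts[:, self.slices["zero_intercept"]] += math.log(zf / (1 - zf))
        if self.y_pos.size:
            base = float(np.mean(self.y_pos))
            pts[:, self.slices["intercept"]] += math.log(max(base, 1e-3))
        pts[:, self.slices[f"log_{self.aux_name}"]] += math.log(1.0)
        for re in self.random_effects:
            pts[:, self.slices[f"log_sigma_{re.name}"]] += math.log(1.0 if self.spec.centered else 0.5)
            if self.spec.centered:
                pts[:, self.slices[f"z_{re.name}"]] *= 5.0
        return pts

    def simulate_response(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one replicate response vector at a single parameter point.

        Random intercepts are held at their (non-centred) values in
        ``theta`` — a conditional replication, as used in posterior
        predictive checks.
        """
        t2 = np.atleast_2d(np.asarray(theta, float))
        if t2.shape[0] != 1:
            raise ValueError("simulate_response expects a single parameter vector")
        eta = self._linear_predictor(t2)[0]
        aux = float(np.exp(t2[0, self.slices[f"log_{self.aux_name}"]][0]))
        mu = np.exp(eta)
        fam = self.spec.family
        if fam == "negbin":
            return rng.negative_binomial(aux, aux / (aux + mu)).astype(float)
        if fam == "gamma":
            return rng.gamma(aux, mu / aux)
        gz = np.array([t2[0, self.slices[n]][0] for n in self.zero_names])
        p_zero = 1.0 / (1.0 + np.exp(-(self.X_zero @ gz)))
        y = np.zeros(self.n_obs)
        nonzero = rng.random(self.n_obs) >= p_zero
        # positive-part eta applies to the observed positive rows; replicate
        # positives on the rows the hurdle leaves nonzero using the marginal
        # positive-mean structure evaluated on those rows
        mu_full = np.full(self.n_obs, np.nan)
        mu_full[self._pos_rows] = mu
        # rows that were zero in the data have no fitted random-effect value;
        # fall back to the fixed-effect mean there
        beta = np.array([t2[0, self.slices[n]][0] for n in self.pos_names])
        Xall = self._full_pos_design
        mu_fallback = np.exp(Xall @ beta)
        mu_full = np.where(np.isnan(mu_full), mu_fallback, mu_full)
        y[nonzero] = rng.gamma(aux, mu_full[nonzero] / aux)
        return y


def build_model(
    spec: ModelSpec, data: pd.DataFrame, priors: PriorConfig | None = None
) -> HierarchicalModel:
    """Construct the joint log-posterior for a model spec over a data table.

    Raises
    ------
    KeyError
        If any term, zero-term, grouping or response column is absent,
        naming the missing column.
    """
    return HierarchicalModel(spec, data, priors)


# ---------------------------------------------------------------------------
# posterior container, fitting, summaries
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Labelled posterior draws plus sampler metadata and diagnostics.

    ``draws`` maps parameter names (natural scale: ``sigma_*`` and
    ``shape``/``dispersion`` are exponentiated) to arrays of shape
    ``(chain, draw)`` or ``(chain, draw, n_levels)``.
    """

    draws: dict[str, np.ndarray]
    chains: int
    warmup: int
    iterations: int
    seed: int
    diagnostics: pd.DataFrame
    converged: bool
    max_rhat: float
    min_ess: float

    def get(self, name: str) -> np.ndarray:
        """Flattened draws for one parameter: (n_total,) or (n_total, L)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:]) if a.ndim > 2 else a.ravel()

    @property
    def n_draws(self) -> int:
        return self.chains * self.iterations

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def to_frame(self) -> pd.DataFrame:
        """One row per chain-iteration, one column per scalar parameter."""
        cols = {}
        for k, v in self.draws.items():
            if v.ndim == 2:
                cols[k] = v.ravel()
            else:
                for j in range(v.shape[2]):
                    cols[f"{k}[{j}]"] = v[:, :, j].ravel()
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(np.arange(self.chains), self.iterations))
        frame.insert(1, "draw", np.tile(np.arange(self.iterations), self.chains))
        return frame

    def save(self, path) -> None:
        """Persist draws (CSV) plus a diagnostics sidecar (CSV)."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        side = self.diagnostics.copy()
        side.attrs = {}
        side.to_csv(path.replace(".csv", "") + "_diagnostics.csv", index=False)


def _diagnostics(draw_dict: dict[str, np.ndarray]) -> pd.DataFrame:
    from .diagnostics import ess_bulk, ess_tail, split_rhat

    rows = []
    for name, a in draw_dict.items():
        r = np.atleast_1d(split_rhat(a))
        eb = np.atleast_1d(ess_bulk(a))
        et = np.atleast_1d(ess_tail(a))
        if r.size == 1:
            rows.append((name, float(r[0]), float(eb[0]), float(et[0])))
        else:
            for j in range(r.size):
                rows.append((f"{name}[{j}]", float(r[j]), float(eb[j]), float(et[j])))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk", "ess_tail"])


def fit(
    model: HierarchicalModel,
    *,
    chains: int = 4,
    warmup: int = 1000,
    iterations: int = 1000,
    seed: int,
    nwalkers: int | None = None,
    thin: int | None = None,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
) -> PosteriorDraws:
    """Sample the posterior with a differential-evolution ensemble sampler.

    The ensemble's walkers act as diagnostic chains; ``chains`` sets a
    floor on the ensemble size (``nwalkers >= max(2*ndim + 2, 8*chains)``).
    ``iterations`` counts post-warmup sampler steps; the stored chain is
    thinned (default: to about 250 draws per walker) since the ensemble
    already supplies many walkers.  If any split-R-hat exceeds
    ``rhat_max`` or any ESS falls below ``ess_min``, the result is
    returned with ``converged=False`` and a :class:`ConvergenceWarning`
    is emitted — never silently.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible fits")
    ndim = model.ndim
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 8 * chains)
    nwalkers += nwalkers % 2

    rng = np.random.default_rng(seed)
    p0 = model.initial_points(rng, nwalkers)
    lp0 = model.log_posterior(p0)
    for _ in range(50):
        bad = ~np.isfinite(lp0)
        if not bad.any():
            break
        p0[bad] = model.initial_points(rng, int(bad.sum()))
        lp0 = model.log_posterior(p0)
    if not np.all(np.isfinite(lp0)):
        j = int(np.argmax(~np.isfinite(lp0)))
        raise ValueError(
            "log-posterior non-finite at initialization; first failing point: "
            + ", ".join(f"{n}={v:.3g}" for n, v in zip(model.param_names, p0[j]))
        )

    sampler = emcee.EnsembleSampler(
        nwalkers,
        ndim,
        model.log_posterior,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.9), (emcee.moves.DESnookerMove(), 0.1)],
    )
    sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True, store=False)
    sampler.reset()
    if thin is None:
        thin = max(1, iterations // 250)
    sampler.run_mcmc(
        state, max(1, iterations // thin), thin_by=thin, skip_initial_state_check=True
    )
    chain = np.moveaxis(sampler.get_chain(), 0, 1)  # (walker, draw, ndim)

    draws: dict[str, np.ndarray] = {}
    for n in model.zero_names + model.pos_names:
        draws[n] = chain[:, :, model.slices[n]][:, :, 0]
    draws[model.aux_name] = np.exp(chain[:, :, model.slices[f"log_{model.aux_name}"]][:, :, 0])
    for re in model.random_effects:
        draws[f"sigma_{re.name}"] = np.exp(
            chain[:, :, model.slices[f"log_sigma_{re.name}"]][:, :, 0]
        )
        draws[f"z_{re.name}"] = chain[:, :, model.slices[f"z_{re.name}"]]

    diag = _diagnostics(draws)
    max_rhat = float(np.nanmax(diag["rhat"]))
    min_ess = float(np.nanmin(diag["ess_bulk"]))
    converged = bool(max_rhat <= rhat_max and min_ess >= ess_min)
    if not converged:
        warnings.warn(
            f"sampler convergence not reached: max split-R-hat {max_rhat:.3f} "
            f"(threshold {rhat_max}), min bulk ESS {min_ess:.0f} (threshold {ess_min:.0f})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return PosteriorDraws(
        draws=draws,
        chains=nwalkers,
        warmup=warmup,
        iterations=chain.shape[1],
        seed=seed,
        diagnostics=diag,
        converged=converged,
        max_rhat=max_rhat,
        min_ess=min_ess,
    )


# ---------------------------------------------------------------------------
# evidence summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceSummary:
    """Directional summary of one parameter's posterior."""

    parameter: str
    median: float
    ci60: tuple[float, float]
    ci95: tuple[float, float]
    prob_above_zero: float  # percent, 0-100
    evidence_class: str  # "none" | ">80%" | ">95%"


def classify_evidence(prob_above_zero: float) -> str:
    """Strict thresholds on percent posterior mass above zero."""
    if prob_above_zero > 95.0:
        return ">95%"
    if prob_above_zero > 80.0:
        return ">80%"
    return "none"


def summarize(draws, parameter: str | None = None, *, min_draws: int = 1000) -> EvidenceSummary:
    """Median, 60%/95% equal-tailed credible intervals, and evidence class.

    ``draws`` may be a :class:`PosteriorDraws` (with ``parameter`` naming a
    scalar entry) or a flat array of draws.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, float).ravel()
        parameter = parameter or "value"
    if x.ndim != 1:
        raise ValueError(f"parameter {parameter!r} is not scalar")
    if x.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {x.size}")
    q = np.quantile(x, [0.025, 0.2, 0.5, 0.8, 0.975])
    prob = 100.0 * float(np.mean(x > 0))
    return EvidenceSummary(
        parameter=parameter,
        median=float(q[2]),
        ci60=(float(q[1]), float(q[3])),
        ci95=(float(q[0]), float(q[4])),
        prob_above_zero=prob,
        evidence_class=classify_evidence(prob),
    )


# ---------------------------------------------------------------------------
# posterior predictive check for excess zeros
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZeroFractionPPC:
    """Observed zero fraction against its posterior predictive distribution."""

    observed: float
    replicated: np.ndarray
    prob_ge: float  # P(replicated zero fraction >= observed)
    prob_le: float

    @property
    def tail_prob(self) -> float:
        return min(self.prob_ge, self.prob_le)


def ppc_zero_fraction(
    posterior: PosteriorDraws,
    model: HierarchicalModel,
    *,
    n_rep: int = 200,
    seed: int = 0,
) -> ZeroFractionPPC:
    """Posterior predictive check of the zero fraction.

    Simulates replicate datasets at parameter draws sampled from the
    posterior and compares the observed fraction of exact zeros with its
    replicated distribution.  A tiny upper-tail probability means the
    data hold more zeros than the fitted model produces (zero inflation).
    """
    if model.n_obs == 0:
        raise ValueError("no observations to check")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, posterior.n_draws, size=n_rep)
    observed = float(np.mean(model.y == 0))
    reps = np.empty(n_rep)
    for k, i in enumerate(idx):
        # reassemble the sampler-scale theta (log aux, log sigma) for draw i
        parts = [
            np.atleast_1d(posterior.get(n)[i])
            for n in model.zero_names + model.pos_names
        ]
        parts.append(np.atleast_1d(np.log(posterior.get(model.aux_name)[i])))
        for re in model.random_effects:
            parts.append(np.atleast_1d(np.log(posterior.get(f"sigma_{re.name}")[i])))
            parts.append(np.atleast_1d(posterior.get(f"z_{re.name}")[i]))
        theta = np.concatenate(parts)
        yrep = model.simulate_response(theta, rng)
        reps[k] = np.mean(yrep == 0)
    prob_ge = float(np.mean(reps >= observed))
    prob_le = float(np.mean(reps <= observed))
    return ZeroFractionPPC(observed=observed, replicated=reps, prob_ge=prob_ge, prob_le=prob_le)
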