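"""Besag-York-Mollie Poisson model, fitted by Metropolis-within-Gibbs MCMC.

Model
-----
For zone ``i`` and outcome window ``w``::

    y_iw ~ Poisson(e_iw * theta_iw),   log theta_iw = alpha + beta * x_iw + u_i + v_i

``theta`` is a standardized incidence ratio: expected counts ``e`` come from
internal indirect standardization (population times the dataset's overall
rate, pooled across windows), so ``sum(e) == sum(y)`` exactly.  ``v_i`` is an
IID normal effect with variance ``sigma_v2``; ``u_i`` is an intrinsic CAR
(ICAR) spatial effect with conditional distribution
``u_i | u_-i ~ N(mean of neighbours, sigma_u2 / n_neighbours)``, identified
by a sum-to-zero constraint.  Hyperpriors are inverse-gamma on the variances
(shape/rate parameterization); ``alpha`` and ``beta`` get vague normal priors.
The random effects are indexed by zone only and shared across that zone's
repeated windows.

Sampling
--------
Conjugate inverse-gamma Gibbs updates for the two variances; adaptive
random-walk Metropolis (targeting 0.44 acceptance, adaptation frozen after
burn-in) for ``alpha``, ``beta`` and each ``u_i``, ``v_i``.  The ``u`` field
is updated in graph-colouring blocks (no two adjacent zones in a block) so
block members are conditionally independent and can be vectorized; after
each sweep ``u`` is re-centred to sum to zero with the offset absorbed into
``alpha``.  Zones with no neighbours (islands) have ``u`` fixed at 0 and are
excluded from the ICAR quadratic form, whose degrees of freedom are
``n - (number of connected components)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .prep import PreparedDataset


@dataclass(frozen=True)
class BYMConfig:
    """Sampler and prior settings.

    Hyperpriors are inverse-gamma (shape, rate) on the variances; the
    fixed-effect prior is normal with mean zero and a large variance.
    ``rr_scale`` is the rainfall increment (mm) used to scale rate ratios.
    """

    hyperprior_v: tuple[float, float] = (0.001, 0.001)
    hyperprior_u: tuple[float, float] = (0.1, 0.1)
    fixed_effect_var: float = 1e6
    chains: int = 2
    iterations: int = 4000
    burn_in: int = 2000
    thinning: int = 2
    seed: int = 0
    rr_scale: float = 0.5
    per_window_expected: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.rr_scale <= 0:
            raise ValueError("rr_scale must be positive")


@dataclass(frozen=True)
class RateRatioEstimate:
    """Posterior rate ratio per ``scale`` mm of mean daily rainfall."""

    rr: float
    ci_low: float
    ci_high: float
    scale: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.ci_high):
            raise ValueError("credible interval must be positive and ordered")

    @property
    def contains_null(self) -> bool:
        return self.ci_low <= 1.0 <= self.ci_high


def compute_expected(
    y: np.ndarray | pd.Series,
    pop: np.ndarray | pd.Series,
    window_id: np.ndarray | pd.Series | None = None,
    per_window: bool = False,
) -> np.ndarray:
    """Expected counts by internal indirect standardization.

    ``e = pop * (sum(y) / sum(pop))`` pooled across all windows of the
    dataset (one gender, one arrangement), so that ``sum(e) == sum(y)``.
    With ``per_window=True`` the rate is computed within each window instead
    (a sensitivity option).
    """
    y = np.asarray(y, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if not np.any(pop > 0):
        raise ValueError("at least one row must have positive population")
    if y.sum() <= 0:
        raise ValueError(
            "all event counts are zero; the model is unidentifiable "
            "(enlarge the simulation rate or pool more data)"
        )
    if per_window:
        if window_id is None:
            raise ValueError("per-window standardization requires window ids")
        df = pd.DataFrame({"y": y, "pop": pop, "w": np.asarray(window_id)})
        rate = df.groupby("w").transform("sum")
        return (pop * (rate["y"] / rate["pop"])).to_numpy()
    return pop * (y.sum() / pop.sum())


def variance_gibbs(
    rng: np.random.Generator,
    shape: float,
    rate: float,
    dof: float,
    sum_sq: float,
) -> float:
    """Conjugate inverse-gamma draw for a random-effect variance.

    With an InvGamma(shape, rate) prior on the variance and a Gaussian
    quadratic form ``sum_sq`` on ``dof`` effective dimensions, the full
    conditional is InvGamma(shape + dof/2, rate + sum_sq/2).
    """
    return max(1.0 / rng.gamma(shape + 0.5 * dof, 1.0 / (rate + 0.5 * sum_sq)), 1e-12)


def zone_adjacency(zonation, lattice) -> nx.Graph:
    """Zone-level neighbour relation: zones are adjacent iff some base unit
    of one is adjacent to some base unit of the other."""
    labels = np.asarray(zonation.labels)
    g = nx.Graph()
    g.add_nodes_from(int(z) for z in np.unique(labels[labels >= 0]))
    for a, b in lattice.graph.edges:
        za, zb = int(labels[a]), int(labels[b])
        if za != zb and za >= 0 and zb >= 0:
            g.add_edge(za, zb)
    return g


def rr_from_posterior(beta_samples: np.ndarray, scale: float) -> RateRatioEstimate:
    """Posterior mean and equal-tailed 95% interval of ``exp(beta * scale)``."""
    beta_samples = np.asarray(beta_samples, dtype=float).ravel()
    if beta_samples.size == 0:
        raise ValueError("posterior sample is empty")
    rr = np.exp(beta_samples * scale)
    lo, hi = np.percentile(rr, [2.5, 97.5])
    return RateRatioEstimate(rr=float(rr.mean()), ci_low=float(lo), ci_high=float(hi), scale=scale)


class BYMModel:
    """Besag-York-Mollie Poisson model for one prepared dataset.

    Parameters
    ----------
    data
        DataFrame with columns ``zone, window_id, y, pop, x`` (``e`` optional;
        computed by indirect standardization when absent or NaN).  Rows with
        zero population are excluded (their count is recorded in the results'
        diagnostics).
    adjacency
        Zone-level neighbour graph (see :func:`zone_adjacency`).
    config
        :class:`BYMConfig`; defaults are used when omitted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        adjacency: nx.Graph,
        config: BYMConfig | None = None,
    ) -> None:
        self.config = config or BYMConfig()
        df = data.copy()
        required = {"zone", "window_id", "y", "pop", "x"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"data missing columns {sorted(missing)}")
        self.n_dropped = int((df["pop"] <= 0).sum())
        df = df[df["pop"] > 0].reset_index(drop=True)
        if "e" not in df.columns or df["e"].isna().any():
            df["e"] = compute_expected(
                df["y"], df["pop"], df["window_id"],
                per_window=self.config.per_window_expected,
            )
        if not np.isfinite(df[["y", "e", "x"]].to_numpy()).all():
            bad = df.index[~np.isfinite(df[["y", "e", "x"]]).all(axis=1)][0]
            raise ValueError(f"non-finite value in row {bad}")
        self.data = df

        self.zone_ids = np.sort(df["zone"].unique())
        self._zidx = {z: i for i, z in enumerate(self.zone_ids)}
        self.n_zones = len(self.zone_ids)
        self.adjacency = adjacency.subgraph([int(z) for z in self.zone_ids]).copy()
        self.islands = sorted(
            int(z) for z in self.adjacency.nodes if self.adjacency.degree(z) == 0
        )

    @classmethod
    def from_prepared(
        cls, prepared: PreparedDataset, adjacency: nx.Graph, config: BYMConfig | None = None
    ) -> "BYMModel":
        return cls(prepared.data, adjacency, config)

    # ------------------------------------------------------------------ #

    def fit(self, seed: int | None = None, **overrides) -> "BYMResults":
        """Run the MCMC and return a :class:`BYMResults`.

        ``overrides`` may replace any :class:`BYMConfig` field for this fit
        (e.g. ``iterations=1000, chains=1``).
        """
        cfg = replace(self.config, **overrides) if overrides else self.config
        if seed is None:
            seed = cfg.seed
        chains = []
        diags = []
        for c in range(cfg.chains):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(c,))
            rng = np.random.default_rng(ss)
            samp, diag = self._run_chain(cfg, rng)
            chains.append(samp)
            diags.append(diag)
        samples = {
            k: np.stack([ch[k] for ch in chains]) for k in chains[0]
        }
        res = BYMResults(model=self, config=cfg, samples=samples, chain_diagnostics=diags)
        res._warn_on_poor_acceptance()
        return res

    # ------------------------------------------------------------------ #

    def _run_chain(self, cfg: BYMConfig, rng: np.random.Generator):
        df = self.data
        y = df["y"].to_numpy(float)
        e = df["e"].to_numpy(float)
        x = df["x"].to_numpy(float)
        zidx = df["zone"].map(self._zidx).to_numpy()
        n = self.n_zones
        xbar = x.mean()
        xc = x - xbar
        y_tot = y.sum()
        yx = (y * xc).sum()
        Y = np.bincount(zidx, weights=y, minlength=n)

        g = self.adjacency
        id_of = self.zone_ids
        nbr = [np.array([self._zidx[j] for j in g.neighbors(int(id_of[i]))], dtype=int)
               for i in range(n)]
        deg = np.array([len(a) for a in nbr], dtype=float)
        free = deg > 0                       # islands have u fixed at 0
        comps = list(nx.connected_components(g))
        icar_rank = n - len(comps)
        edges = np.array([[self._zidx[a], self._zidx[b]] for a, b in g.edges], dtype=int)
        colors = nx.greedy_color(g)
        color_groups = []
        for col in sorted(set(colors.values())):
            grp = np.array(
                [self._zidx[z] for z, cc in colors.items() if cc == col and free[self._zidx[z]]],
                dtype=int,
            )
            if grp.size:
                color_groups.append(grp)

        a_v, b_v = cfg.hyperprior_v
        a_u, b_u = cfg.hyperprior_u
        prior_var = cfg.fixed_effect_var

        alpha, beta = 0.0, 0.0
        u = np.zeros(n)
        v = np.zeros(n)
        s2u, s2v = 0.05, 0.05

        info_b = max((e * xc**2).sum(), 1e-8)
        step_a = 2.4 / np.sqrt(max(e.sum(), 1.0))
        step_b = 2.4 / np.sqrt(info_b)
        step_u = 2.4 / np.sqrt(Y + 1.0)
        step_v = step_u.copy()

        eta = alpha + beta * xc + (u + v)[zidx]
        E = e * np.exp(eta)
        S = np.bincount(zidx, weights=E, minlength=n)

        acc = {"alpha": 0, "beta": 0}
        acc_u = np.zeros(n)
        acc_v = np.zeros(n)
        batch = {"alpha": 0, "beta": 0}
        batch_u = np.zeros(n)
        batch_v = np.zeros(n)
        batch_len = 50
        batch_no = 0

        keep = (cfg.iterations - cfg.burn_in) // cfg.thinning
        out = {
            "alpha": np.empty(keep), "beta": np.empty(keep),
            "sigma_u2": np.empty(keep), "sigma_v2": np.empty(keep),
            "u": np.empty((keep, n)), "v": np.empty((keep, n)),
        }
        kept = 0

        for it in range(cfg.iterations):
            adapting = it < cfg.burn_in

            # alpha: random-walk Metropolis on the pooled Poisson likelihood
            d = rng.normal(0.0, step_a)
            logr = d * y_tot - S.sum() * np.expm1(d)
            logr += (alpha**2 - (alpha + d) ** 2) / (2 * prior_var)
            if np.log(rng.uniform()) < logr:
                alpha += d
                f = np.exp(d)
                E *= f
                S *= f
                acc["alpha"] += 1
                batch["alpha"] += 1

            # beta
            d = rng.normal(0.0, step_b)
            fvec = np.exp(d * xc)
            logr = d * yx - (E * (fvec - 1.0)).sum()
            logr += (beta**2 - (beta + d) ** 2) / (2 * prior_var)
            if np.log(rng.uniform()) < logr:
                beta += d
                E *= fvec
                S = np.bincount(zidx, weights=E, minlength=n)
                acc["beta"] += 1
                batch["beta"] += 1

            # u: colouring-block Metropolis against Poisson x ICAR conditional
            if icar_rank > 0:
                for grp in color_groups:
                    nb_sum = np.array([u[nbr[i]].sum() for i in grp])
                    m = nb_sum / deg[grp]
                    d = rng.normal(0.0, step_u[grp])
                    new = u[grp] + d
                    logr = d * Y[grp] - S[grp] * np.expm1(d)
                    logr += (deg[grp] / (2 * s2u)) * ((u[grp] - m) ** 2 - (new - m) ** 2)
                    ok = np.log(rng.uniform(size=grp.size)) < logr
                    if ok.any():
                        sel = grp[ok]
                        u[sel] = new[ok]
                        fac = np.exp(d[ok])
                        S[sel] *= fac
                        zf = np.ones(n)
                        zf[sel] = fac
                        E *= zf[zidx]
                        acc_u[sel] += 1
                        batch_u[sel] += 1
                # re-centre: absorb the offset into alpha (likelihood invariant)
                m0 = u[free].mean()
                if free.all():
                    u -= m0
                    alpha += m0
                else:
                    # islands stay at 0; centre the free block only (the small
                    # per-sweep drift is not absorbable into a single intercept)
                    u[free] -= m0

            # v: all zones in parallel (independent priors and likelihoods)
            d = rng.normal(0.0, step_v)
            new = v + d
            logr = d * Y - S * np.expm1(d) + (v**2 - new**2) / (2 * s2v)
            ok = np.log(rng.uniform(size=n)) < logr
            if ok.any():
                sel = np.flatnonzero(ok)
                fac = np.exp(d[sel])
                v[sel] = new[sel]
                S[sel] *= fac
                zf = np.ones(n)
                zf[sel] = fac
                E *= zf[zidx]
                acc_v[sel] += 1
                batch_v[sel] += 1

            # conjugate variance updates
            s2v = variance_gibbs(rng, a_v, b_v, n, (v**2).sum())
            if icar_rank > 0:
                quad = ((u[edges[:, 0]] - u[edges[:, 1]]) ** 2).sum()
                s2u = variance_gibbs(rng, a_u, b_u, icar_rank, quad)
            else:
                s2u = variance_gibbs(rng, a_u, b_u, 0.0, 0.0)

            # step-size adaptation during burn-in (frozen afterwards)
            if adapting and (it + 1) % batch_len == 0:
                batch_no += 1
                delta = min(0.1, batch_no ** -0.5)
                step_a *= np.exp(delta if batch["alpha"] / batch_len > 0.44 else -delta)
                step_b *= np.exp(delta if batch["beta"] / batch_len > 0.44 else -delta)
                step_u *= np.exp(np.where(batch_u / batch_len > 0.44, delta, -delta))
                step_v *= np.exp(np.where(batch_v / batch_len > 0.44, delta, -delta))
                batch = {"alpha": 0, "beta": 0}
                batch_u[:] = 0.0
                batch_v[:] = 0.0
                acc = {"alpha": 0, "beta": 0}
                acc_u[:] = 0.0
                acc_v[:] = 0.0
                # refresh running quantities to stop numerical drift
                eta = alpha + beta * xc + (u + v)[zidx]
                E = e * np.exp(eta)
                S = np.bincount(zidx, weights=E, minlength=n)

            if not adapting and (it - cfg.burn_in) % cfg.thinning == 0 and kept < keep:
                out["alpha"][kept] = alpha - beta * xbar  # undo covariate centring
                out["beta"][kept] = beta
                out["sigma_u2"][kept] = s2u
                out["sigma_v2"][kept] = s2v
                out["u"][kept] = u
                out["v"][kept] = v
                kept += 1

        post_iters = cfg.iterations - cfg.burn_in
        diag = {
            "accept_alpha": acc["alpha"] / post_iters,
            "accept_beta": acc["beta"] / post_iters,
            "accept_u": (acc_u[free] / post_iters).mean() if free.any() else np.nan,
            "accept_v": (acc_v / post_iters).mean(),
            "n_dropped_rows": self.n_dropped,
            "islands": self.islands,
        }
        return out, diag


class BYMResults:
    """Posterior samples and diagnostics from a :class:`BYMModel` fit.

    ``samples`` maps parameter names to arrays of shape ``(chains, draws)``
    (or ``(chains, draws, n_zones)`` for the random-effect fields).
    """

    def __init__(self, model: BYMModel, config: BYMConfig, samples: dict, chain_diagnostics):
        self.model = model
        self.config = config
        self.samples = samples
        self.chain_diagnostics = chain_diagnostics

    def _flat(self, name: str) -> np.ndarray:
        s = self.samples[name]
        return s.reshape(-1, *s.shape[2:])

    @property
    def posterior_mean(self) -> dict[str, float]:
        return {
            k: float(self._flat(k).mean(axis=0).mean()) if self.samples[k].ndim > 2
            else float(self._flat(k).mean())
            for k in ("alpha", "beta", "sigma_u2", "sigma_v2")
        }

    def rate_ratio(self, scale: float | None = None) -> RateRatioEstimate:
        """Scaled posterior rate ratio ``exp(beta * scale)`` with 95% CrI."""
        return rr_from_posterior(self._flat("beta"), scale or self.config.rr_scale)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, quantiles and effective sample size."""
        import arviz as az

        rows = []
        for name in ("alpha", "beta", "sigma_u2", "sigma_v2"):
            s = self.samples[name]
            flat = s.ravel()
            ess = float(az.ess(az.convert_to_dataset(s))["x"].mean())
            rows.append(
                {
                    "param": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.percentile(flat, 2.5),
                    "q50": np.percentile(flat, 50),
                    "q97.5": np.percentile(flat, 97.5),
                    "ess": ess,
                }
            )
        return pd.DataFrame(rows)

    def _warn_on_poor_acceptance(self) -> None:
        for c, d in enumerate(self.chain_diagnostics):
            for k in ("accept_alpha", "accept_beta", "accept_u", "accept_v"):
                r = d[k]
                if np.isfinite(r) and not (0.05 <= r <= 0.95):
                    warnings.warn(
                        f"chain {c}: acceptance rate for {k[7:]} block is {r:.3f}, "
                        f"outside [0.05, 0.95]; diagnostics: {d}",
                        RuntimeWarning,
                        stacklevel=3,
                    )
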