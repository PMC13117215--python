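"""Bayesian network meta-analysis over treatment regimens.

Because every included study is single-arm, the default model is arm-based:
logit(p_arm) = m + d_t(arm) + u_study with a study-level random effect
u ~ N(0, sigma^2) and the reference treatment's d fixed at 0.  A
contrast-based consistency model (Lu-Ades style, for networks that do
contain multi-arm studies) is also provided.  Ranking uses draw-wise
ordering of the treatment effects to build the rank-probability matrix,
from which SUCRA values follow; consistency is assessed by node splitting
(separate direct- versus indirect-evidence fits and the two-sided Bayesian
p of their difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .bayes_meta import McmcSettings, PriorSpec, _ci_summary, _log1pexp, \
    _rhat_ess

__all__ = [
    "NetworkData",
    "NmaResult",
    "NodeSplitResult",
    "fit_nma",
    "sucra_from_ranks",
    "node_split",
]


@dataclass(frozen=True)
class NetworkData:
    """Arm-level binary outcome data for a treatment network."""

    arms: tuple[tuple[str, str, int, int], ...]  # (study, treatment, x, n)
    reference: str
    direction: str = "higher_better"
    strata: Mapping[str, str] | None = None  # study_id -> stratum key

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError("direction must be higher_better or lower_better")
        for s, t, x, n in self.arms:
            if not 0 <= x <= n:
                raise ValueError(f"events exceed total in {s}/{t}")
        if self.reference not in self.treatments:
            raise ValueError(f"reference {self.reference!r} not in network")

    @property
    def treatments(self) -> tuple[str, ...]:
        seen = dict.fromkeys(t for _, t, _, _ in self.arms)
        return tuple(seen)

    @property
    def studies(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s for s, _, _, _ in self.arms))

    def connectivity_graph(self) -> nx.Graph:
        """Bipartite-projected study/treatment graph used for connectivity.

        Treatments are connected when they co-occur in a study or — for
        single-arm networks — when their studies share a stratum.
        """
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for sid in self.studies:
            ts = [t for s, t, _, _ in self.arms if s == sid]
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    g.add_edge(ts[i], ts[j])
        if self.strata:
            by_stratum: dict[str, set[str]] = {}
            for s, t, _, _ in self.arms:
                st = self.strata.get(s)
                if st is not None:
                    by_stratum.setdefault(st, set()).add(t)
            for ts in by_stratum.values():
                ts = sorted(ts)
                for i in range(len(ts)):
                    for j in range(i + 1, len(ts)):
                        g.add_edge(ts[i], ts[j])
        return g

    def check_connected(self, via_common_intercept: bool = True) -> None:
        """Raise listing components when the network is disconnected.

        In the arm-based model all treatments share the study-level intercept
        distribution, so with ``via_common_intercept`` an all-single-arm
        network counts as connected as long as every treatment has data;
        without it, co-occurrence/stratum edges are required.
        """
        if via_common_intercept:
            return
        g = self.connectivity_graph()
        comps = list(nx.connected_components(g))
        if len(comps) > 1:
            raise ValueError(
                "disconnected network; components: "
                + "; ".join(sorted(",".join(sorted(c)) for c in comps)))


@dataclass
class NmaResult:
    """Treatment-effect posteriors, rank probabilities and SUCRA values."""

    treatments: tuple[str, ...]
    d: np.ndarray  # (chains, draws, T), reference column all zeros
    sigma: np.ndarray
    rank_probs: np.ndarray  # (T, T): P(treatment t has rank r)
    sucra: dict
    summaries: dict
    diagnostics: dict
    direction: str
    model: str

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("max_rhat", np.inf) <= 1.05)


@dataclass
class NodeSplitResult:
    comparison: tuple[str, str]
    direct: dict
    indirect: dict
    difference: dict
    p_value: float


def _rank_matrix(d_flat: np.ndarray, direction: str, rng) -> np.ndarray:
    """Draw-wise rank probabilities; rank 1 = best under the direction."""
    vals = d_flat if direction == "higher_better" else -d_flat
    # measure-zero ties broken by random jitter
    vals = vals + 1e-12 * rng.standard_normal(vals.shape)
    order = np.argsort(-vals, axis=1)
    n_draws, T = vals.shape
    ranks = np.empty_like(order)
    rows = np.arange(n_draws)[:, None]
    ranks[rows, order] = np.arange(T)[None, :]
    probs = np.zeros((T, T))
    for r in range(T):
        probs[:, r] = (ranks == r).mean(axis=0)
    return probs


def sucra_from_ranks(rank_probs: np.ndarray) -> np.ndarray:
    """SUCRA_t = sum over r < T of CumP(rank <= r) / (T - 1).

    Rows must sum to 1; the values sum to T/2 across treatments by
    construction.
    """
    rp = np.asarray(rank_probs, dtype=float)
    if rp.ndim != 2 or rp.shape[0] != rp.shape[1]:
        raise ValueError("rank matrix must be square")
    if not np.allclose(rp.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rank-matrix rows must sum to 1")
    T = rp.shape[0]
    cum = np.cumsum(rp, axis=1)
    return cum[:, : T - 1].sum(axis=1) / (T - 1)


def fit_nma(
    data: NetworkData,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    model: str = "arm_based",
) -> NmaResult:
    """Sample the network posterior and derive ranks and SUCRA.

    ``arm_based`` (default, required when every study is single-arm) places
    treatment effects on the arm logits with a study random effect;
    ``contrast_based`` is the standard consistency model on within-study
    contrasts and refuses all-single-arm data.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    multi = [s for s in data.studies
             if sum(1 for a in data.arms if a[0] == s) > 1]
    if model == "contrast_based":
        if not multi:
            raise ValueError(
                "contrast_based needs multi-arm studies; this network is "
                "all single-arm — use model='arm_based'")
        return _fit_contrast(data, prior, mcmc)
    if model != "arm_based":
        raise ValueError(f"unknown model {model!r}")
    data.check_connected(via_common_intercept=True)
    return _fit_arm_based(data, prior, mcmc)


def _fit_arm_based(data: NetworkData, prior: PriorSpec,
                   mcmc: McmcSettings) -> NmaResult:
    treatments = data.treatments
    studies = data.studies
    T, S = len(treatments), len(studies)
    t_idx = {t: i for i, t in enumerate(treatments)}
    s_idx = {s: i for i, s in enumerate(studies)}
    ref = t_idx[data.reference]
    A = len(data.arms)
    x = np.array([a[2] for a in data.arms], dtype=float)
    n = np.array([a[3] for a in data.arms], dtype=float)
    arm_t = np.array([t_idx[a[1]] for a in data.arms])
    arm_s = np.array([s_idx[a[0]] for a in data.arms])

    C = mcmc.n_chains
    rng = np.random.default_rng(mcmc.seed)
    logit_obs = np.log((x + 0.5) / (n - x + 0.5))
    m = np.full(C, logit_obs.mean()) + rng.normal(0, 0.1, C)
    d = np.zeros((C, T))
    u = rng.normal(0, 0.1, (C, S))
    sigma = np.full(C, 0.5)
    step_m = np.full(C, 0.3)
    step_d = np.full((C, T), 0.3)
    step_u = np.full((C, S), 0.5)
    step_sig = np.full(C, 0.5)
    prec0 = 1.0 / prior.mu_scale**2
    target = mcmc.target_accept
    keep = mcmc.n_iter - mcmc.n_burnin
    out_d = np.empty((C, keep, T))
    out_sig = np.empty((C, keep))
    out_m = np.empty((C, keep))

    def arm_ll(eta):
        return x * eta - n * _log1pexp(eta)

    for it in range(mcmc.n_iter):
        adapt = it < mcmc.n_burnin
        gamma = 1.0 / math.sqrt(it + 1)
        eta = m[:, None] + d[:, arm_t] + u[:, arm_s]
        ll_arm = arm_ll(eta)

        # overall intercept
        prop = m + step_m * rng.normal(size=C)
        eta_p = prop[:, None] + d[:, arm_t] + u[:, arm_s]
        lp_cur = ll_arm.sum(axis=1) - 0.5 * prec0 * m**2
        lp_new = arm_ll(eta_p).sum(axis=1) - 0.5 * prec0 * prop**2
        acc = np.log(rng.random(C)) < lp_new - lp_cur
        m = np.where(acc, prop, m)
        if adapt:
            step_m *= np.exp(gamma * (acc.astype(float) - target))

        # treatment effects (reference pinned at 0)
        for t in range(T):
            if t == ref:
                continue
            sel = arm_t == t
            dp = d[:, t] + step_d[:, t] * rng.normal(size=C)
            eta_cur = m[:, None] + d[:, t][:, None] + u[:, arm_s[sel]]
            eta_new = m[:, None] + dp[:, None] + u[:, arm_s[sel]]
            ll_c = (x[sel] * eta_cur - n[sel] * _log1pexp(eta_cur)).sum(axis=1)
            ll_n = (x[sel] * eta_new - n[sel] * _log1pexp(eta_new)).sum(axis=1)
            lp_c = ll_c - 0.5 * prec0 * d[:, t] ** 2
            lp_n = ll_n - 0.5 * prec0 * dp**2
            acc = np.log(rng.random(C)) < lp_n - lp_c
            d[:, t] = np.where(acc, dp, d[:, t])
            if adapt:
                step_d[:, t] *= np.exp(gamma * (acc.astype(float) - target))

        # study random effects, elementwise (each arm belongs to one study;
        # group arm log-likelihoods by study)
        up = u + step_u * rng.normal(size=(C, S))
        eta_cur = m[:, None] + d[:, arm_t] + u[:, arm_s]
        eta_new = m[:, None] + d[:, arm_t] + up[:, arm_s]
        ll_cur_arm = arm_ll(eta_cur)
        ll_new_arm = arm_ll(eta_new)
        sig2 = np.maximum(sigma[:, None] ** 2, 1e-12)
        ll_cur_s = np.zeros((C, S))
        ll_new_s = np.zeros((C, S))
        for a in range(A):
            ll_cur_s[:, arm_s[a]] += ll_cur_arm[:, a]
            ll_new_s[:, arm_s[a]] += ll_new_arm[:, a]
        lp_c = ll_cur_s - u**2 / (2 * sig2)
        lp_n = ll_new_s - up**2 / (2 * sig2)
        acc = np.log(rng.random((C, S))) < lp_n - lp_c
        u = np.where(acc, up, u)
        if adapt:
            step_u *= np.exp(gamma * (acc.astype(float) - target))

        # sigma via RW-MH on log scale, Half-Normal prior
        lsig = np.log(sigma)
        lprop = lsig + step_sig * rng.normal(size=C)
        sprop = np.exp(lprop)
        dev = (u**2).sum(axis=1)
        def lp_sig(s_, ls):
            return (-S * ls - dev / (2 * s_**2)
                    + prior.tau_logpdf(s_) + ls)
        acc = np.log(rng.random(C)) < lp_sig(sprop, lprop) - lp_sig(sigma, lsig)
        sigma = np.where(acc, sprop, sigma)
        if adapt:
            step_sig *= np.exp(gamma * (acc.astype(float) - target))

        if it >= mcmc.n_burnin:
            j = it - mcmc.n_burnin
            out_d[:, j] = d
            out_sig[:, j] = sigma
            out_m[:, j] = m

    return _assemble_nma(data, treatments, ref, out_d, out_sig, out_m,
                         mcmc, "arm_based")


def _assemble_nma(data, treatments, ref, out_d, out_sig, out_m, mcmc,
                  model_name) -> NmaResult:
    T = len(treatments)
    rng = np.random.default_rng(mcmc.seed + 999)
    d_flat = out_d.reshape(-1, T)
    rank_probs = _rank_matrix(d_flat, data.direction, rng)
    sucra = dict(zip(treatments, sucra_from_ranks(rank_probs)))
    summaries = {
        t: _ci_summary(out_d[:, :, i]) for i, t in enumerate(treatments)
        if i != ref
    }
    summaries["sigma"] = _ci_summary(out_sig)
    summaries["m"] = _ci_summary(out_m)
    rhats = [_rhat_ess(out_sig)[0], _rhat_ess(out_m)[0]]
    for i in range(T):
        if i != ref:
            rhats.append(_rhat_ess(out_d[:, :, i])[0])
    diagnostics = {"max_rhat": float(np.nanmax(rhats))}
    return NmaResult(treatments, out_d, out_sig, rank_probs, sucra,
                     summaries, diagnostics, data.direction, model_name)


def _fit_contrast(data: NetworkData, prior: PriorSpec,
                  mcmc: McmcSettings) -> NmaResult:
    """Lu-Ades consistency model on within-study contrasts.

    Multi-arm correlation beyond the first contrast is approximated by
    independent normal random effects per non-baseline arm.
    """
    data.check_connected(via_common_intercept=False)
    treatments = data.treatments
    studies = data.studies
    T, S = len(treatments), len(studies)
    t_idx = {t: i for i, t in enumerate(treatments)}
    s_idx = {s: i for i, s in enumerate(studies)}
    ref = t_idx[data.reference]
    A = len(data.arms)
    x = np.array([a[2] for a in data.arms], dtype=float)
    n = np.array([a[3] for a in data.arms], dtype=float)
    arm_t = np.array([t_idx[a[1]] for a in data.arms])
    arm_s = np.array([s_idx[a[0]] for a in data.arms])
    base_t = np.empty(S, dtype=int)
    for s in range(S):
        base_t[s] = arm_t[arm_s == s][0]
    is_base = np.array([arm_t[a] == base_t[arm_s[a]] for a in range(A)])

    C = mcmc.n_chains
    rng = np.random.default_rng(mcmc.seed)
    mu_s = np.tile(np.log((x + 0.5) / (n - x + 0.5))[is_base][
        np.argsort(arm_s[is_base])], (C, 1))
    delta = np.zeros((C, A))  # only non-baseline entries used
    d = np.zeros((C, T))
    tau = np.full(C, 0.3)
    step_mu = np.full((C, S), 0.4)
    step_delta = np.full((C, A), 0.4)
    step_d = np.full((C, T), 0.3)
    step_tau = np.full(C, 0.5)
    prec0 = 1.0 / prior.mu_scale**2
    target = mcmc.target_accept
    keep = mcmc.n_iter - mcmc.n_burnin
    out_d = np.empty((C, keep, T))
    out_tau = np.empty((C, keep))
    out_mu = np.empty((C, keep, S))

    def eta_all(mu_s_, delta_):
        e = mu_s_[:, arm_s].copy()
        e[:, ~is_base] += delta_[:, ~is_base]
        return e

    nb = np.where(~is_base)[0]

    for it in range(mcmc.n_iter):
        adapt = it < mcmc.n_burnin
        gamma = 1.0 / math.sqrt(it + 1)
        tau2 = np.maximum(tau[:, None] ** 2, 1e-12)
        mean_delta = d[:, arm_t] - d[:, base_t[arm_s]]

        # study baselines
        for s in range(S):
            sel = arm_s == s
            prop = mu_s[:, s] + step_mu[:, s] * rng.normal(size=C)
            eta_c = mu_s[:, s][:, None] + np.where(
                is_base[sel], 0.0, delta[:, sel])
            eta_n = prop[:, None] + np.where(
                is_base[sel], 0.0, delta[:, sel])
            ll_c = (x[sel] * eta_c - n[sel] * _log1pexp(eta_c)).sum(axis=1) \
                - 0.5 * prec0 * mu_s[:, s] ** 2
            ll_n = (x[sel] * eta_n - n[sel] * _log1pexp(eta_n)).sum(axis=1) \
                - 0.5 * prec0 * prop**2
            acc = np.log(rng.random(C)) < ll_n - ll_c
            mu_s[:, s] = np.where(acc, prop, mu_s[:, s])
            if adapt:
                step_mu[:, s] *= np.exp(gamma * (acc.astype(float) - target))

        # contrasts delta for non-baseline arms (independent RE approx)
        if len(nb):
            prop = delta.copy()
            prop[:, nb] += step_delta[:, nb] * rng.normal(size=(C, len(nb)))
            eta_c = eta_all(mu_s, delta)[:, nb]
            eta_n = eta_all(mu_s, prop)[:, nb]
            ll_c = x[nb] * eta_c - n[nb] * _log1pexp(eta_c) \
                - (delta[:, nb] - mean_delta[:, nb]) ** 2 / (2 * tau2)
            ll_n = x[nb] * eta_n - n[nb] * _log1pexp(eta_n) \
                - (prop[:, nb] - mean_delta[:, nb]) ** 2 / (2 * tau2)
            acc = np.log(rng.random((C, len(nb)))) < ll_n - ll_c
            delta[:, nb] = np.where(acc, prop[:, nb], delta[:, nb])
            if adapt:
                step_delta[:, nb] *= np.exp(
                    gamma * (acc.astype(float) - target))

        # basic parameters d_t
        for t in range(T):
            if t == ref:
                continue
            dp = d.copy()
            dp[:, t] = d[:, t] + step_d[:, t] * rng.normal(size=C)
            mean_c = d[:, arm_t] - d[:, base_t[arm_s]]
            mean_n = dp[:, arm_t] - dp[:, base_t[arm_s]]
            dev_c = ((delta[:, nb] - mean_c[:, nb]) ** 2).sum(axis=1)
            dev_n = ((delta[:, nb] - mean_n[:, nb]) ** 2).sum(axis=1)
            lp_c = -dev_c / (2 * tau2[:, 0]) - 0.5 * prec0 * d[:, t] ** 2
            lp_n = -dev_n / (2 * tau2[:, 0]) - 0.5 * prec0 * dp[:, t] ** 2
            acc = np.log(rng.random(C)) < lp_n - lp_c
            d[:, t] = np.where(acc, dp[:, t], d[:, t])
            if adapt:
                step_d[:, t] *= np.exp(gamma * (acc.astype(float) - target))

        # tau
        mean_delta = d[:, arm_t] - d[:, base_t[arm_s]]
        dev = ((delta[:, nb] - mean_delta[:, nb]) ** 2).sum(axis=1)
        ltau = np.log(tau)
        lprop = ltau + step_tau * rng.normal(size=C)
        tprop = np.exp(lprop)
        k_nb = len(nb)
        def lp_tau(t_, lt):
            return -k_nb * lt - dev / (2 * t_**2) + prior.tau_logpdf(t_) + lt
        acc = np.log(rng.random(C)) < lp_tau(tprop, lprop) - lp_tau(tau, ltau)
        tau = np.where(acc, tprop, tau)
        if adapt:
            step_tau *= np.exp(gamma * (acc.astype(float) - target))

        if it >= mcmc.n_burnin:
            j = it - mcmc.n_burnin
            out_d[:, j] = d
            out_tau[:, j] = tau
            out_mu[:, j] = mu_s

    res = _assemble_nma(data, treatments, ref, out_d, out_tau,
                        out_mu.mean(axis=2), mcmc, "contrast_based")
    return res


def node_split(
    data: NetworkData,
    comparison: tuple[str, str],
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> NodeSplitResult:
    """Consistency check separating direct and indirect evidence.

    Direct evidence for (a, b): studies containing both treatments, or — in
    all-single-arm networks — studies of a and b sharing a stratum (the
    configurable ``strata`` map of :class:`NetworkData`).  The direct and
    indirect estimates come from independent fits on the two evidence sets;
    the two-sided Bayesian p is 2 * min(P(diff > 0), P(diff < 0)).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    a, b = comparison
    treatments = data.treatments
    for t in (a, b):
        if t not in treatments:
            raise ValueError(f"treatment {t!r} absent from the network")

    by_study: dict[str, set[str]] = {}
    for s, t, _, _ in data.arms:
        by_study.setdefault(s, set()).add(t)
    direct_studies = {s for s, ts in by_study.items() if a in ts and b in ts}
    if not direct_studies and data.strata:
        by_stratum: dict[str, set[str]] = {}
        for s, ts in by_study.items():
            st = data.strata.get(s)
            if st is not None:
                by_stratum.setdefault(st, set()).update(
                    (s, t) for t in ts)
        for st, pairs in by_stratum.items():
            ts_here = {t for _, t in pairs}
            if a in ts_here and b in ts_here:
                direct_studies.update(
                    s for s, t in pairs if t in (a, b))
    if not direct_studies:
        raise ValueError(
            f"comparison {a} vs {b} has no direct evidence "
            "(no shared study or stratum)")
    indirect_studies = [s for s in data.studies if s not in direct_studies]
    ind_arms = [arm for arm in data.arms if arm[0] in indirect_studies]
    ind_treats = {t for _, t, _, _ in ind_arms}
    if not (a in ind_treats and b in ind_treats):
        raise ValueError(
            f"comparison {a} vs {b} has no indirect evidence "
            "(remaining network lacks one of the treatments)")

    def effect_draws(arms, seed_shift):
        ref = a
        sub = NetworkData(tuple(arms), reference=ref,
                          direction=data.direction, strata=data.strata)
        res = fit_nma(sub, prior, replace(mcmc, seed=mcmc.seed + seed_shift),
                      model="arm_based")
        j = sub.treatments.index(b)
        return res.d[:, :, j].reshape(-1)

    dir_arms = [arm for arm in data.arms if arm[0] in direct_studies
                and arm[1] in (a, b)]
    d_direct = effect_draws(dir_arms, 31)
    d_indirect = effect_draws(ind_arms, 63)
    m = min(len(d_direct), len(d_indirect))
    diff = d_direct[:m] - d_indirect[:m]
    p = 2 * min(float(np.mean(diff > 0)), float(np.mean(diff < 0)))
    p = max(p, 1.0 / m)  # never exactly 0 at finite draws
    return NodeSplitResult(
        comparison=(a, b),
        direct=_ci_summary(d_direct),
        indirect=_ci_summary(d_indirect),
        difference=_ci_summary(diff),
        p_value=min(p, 1.0),
    )
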