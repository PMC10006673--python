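"""Synthetic benchmark: sampled fluxomes, generated transcriptomes, scoring.

Genome-scale fluxomes cannot be measured directly, so method accuracy is
assessed against simulated ground truth: reference fluxomes are drawn
uniformly from the model's steady-state polytope (hit-and-run sampling), and
for each reference a transcriptome is generated in which a fraction
``lambda`` of reactions receives expression proportional to its flux while
the rest receive random (exponential) expression.  ``lambda`` therefore dials
the transcriptome's informativeness from none (0) to perfect (1); sweeping it
and scoring predictions with Pearson correlation — at carbon-core and at
genome scale — reproduces the simulation protocol used to compare the
entropy method against expression-blind FBA.

The module also ships the hand-built fixture networks: the two-metabolite /
four-reaction toy containing a thermodynamically infeasible cycle (TIC), a
linear chain, a parallel-path variant, and a seeded random "flow" network
generator with one-gene-per-reaction GPRs used as a miniature genome-scale
stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UnboundedProblemError, ValidationError
from .expression import ExpressionProfile, map_expression
from .models import FBAMinL2, FluxSolution, Pheflux, Spot
from .network import MetabolicNetwork, split_reversible, to_cobra_model

__all__ = [
    "toy_tic_json_path",
    "toy_tic_network",
    "tic_expression_preset",
    "chain_network",
    "parallel_paths_network",
    "random_flow_network",
    "sample_fluxomes",
    "generate_expression",
    "score_prediction",
    "core_reaction_set",
    "SyntheticBenchmark",
    "make_benchmark",
    "run_lambda_sweep",
]


# ---------------------------------------------------------------------------
# fixture networks
# ---------------------------------------------------------------------------

def toy_tic_json_path() -> str:
    """Path of the packaged JSON serialization of the toy TIC model."""
    from importlib.resources import files

    return str(files("entroflux").joinpath("data/toy_tic.json"))


def toy_tic_network() -> MetabolicNetwork:
    """Two metabolites, four reactions, one thermodynamically infeasible
    cycle: v1 (uptake -> A), v2 (A -> B), v3 (B -> A, closing the cycle with
    v2), v4 (B -> secretion).  One gene per reaction (g1..g4)."""
    S = np.array([
        #  v1  v2  v3  v4
        [1., -1., 1., 0.],   # A
        [0., 1., -1., -1.],  # B
    ])
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["v1", "v2", "v3", "v4"],
        S=S,
        lower_bound=np.zeros(4),
        upper_bound=np.full(4, 1000.0),
        gpr_rules=["g1", "g2", "g3", "g4"],
        subsystems=["Exchange", "Core", "Core", "Exchange"],
    )


#: Expression scenarios for the toy TIC network: equal expression on all
#: reactions; the cycle-closing reaction doubled; and one order of magnitude
#: higher than any other reaction.
_TIC_PRESETS = {
    "equal": {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0},
    "g3_double": {"g1": 1.0, "g2": 1.0, "g3": 2.0, "g4": 1.0},
    "g3_tenfold": {"g1": 1.0, "g2": 1.0, "g3": 10.0, "g4": 1.0},
}


def tic_expression_preset(name: str) -> ExpressionProfile:
    """Named expression scenario for :func:`toy_tic_network`.

    ``"equal"``, ``"g3_double"`` (cycle reaction doubled) or
    ``"g3_tenfold"`` (cycle reaction ten-fold every other reaction).
    """
    try:
        values = _TIC_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_TIC_PRESETS)}"
        ) from None
    return ExpressionProfile(dict(values), sample_id=f"tic_{name}")


def chain_network(length: int = 2) -> MetabolicNetwork:
    """Linear chain: uptake -> M1 -> ... -> secretion (``length`` >= 2
    reactions, ``length - 1`` metabolites); its polytope at fixed total flux
    is a single point, and without the total-flux constraint it is a
    segment."""
    if length < 2:
        raise ValueError("chain needs at least uptake and secretion")
    n_mets = length - 1
    S = np.zeros((n_mets, length))
    for j in range(length):
        if j > 0:
            S[j - 1, j] = -1.0
        if j < n_mets:
            S[j, j] = 1.0
    return MetabolicNetwork(
        metabolite_ids=[f"M{i+1}" for i in range(n_mets)],
        reaction_ids=[f"v{i+1}" for i in range(length)],
        S=S,
        lower_bound=np.zeros(length),
        upper_bound=np.full(length, 1000.0),
        gpr_rules=[f"g{i+1}" for i in range(length)],
        subsystems=["Chain"] * length,
    )


def parallel_paths_network() -> MetabolicNetwork:
    """Toy TIC network plus a parallel A -> B reaction (v5): two free
    dimensions remain after fixing the total flux, small enough for dense
    grid-search oracles."""
    S = np.array([
        #  v1  v2  v3  v4  v5
        [1., -1., 1., 0., -1.],  # A
        [0., 1., -1., -1., 1.],  # B
    ])
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["v1", "v2", "v3", "v4", "v5"],
        S=S,
        lower_bound=np.zeros(5),
        upper_bound=np.full(5, 1000.0),
        gpr_rules=["g1", "g2", "g3", "g4", "g5"],
        subsystems=["Exchange", "Core", "Core", "Exchange", "Core"],
    )


def random_flow_network(n_metabolites: int = 18, n_extra: int = 24,
                        reversible_frac: float = 0.2,
                        uptake_ub: float = 10.0,
                        seed: int = 0) -> MetabolicNetwork:
    """Seeded random unit-stoichiometry network (a flow network).

    Metabolites are nodes; every reaction moves one unit between two nodes
    (or across the boundary), so steady state is flow conservation.  The
    network is a chain backbone (uptake -> M1 -> ... -> Mk -> secretion)
    plus ``n_extra`` random internal edges, a fraction of them reversible —
    these create the parallel routes and thermodynamically infeasible
    cycles that genome-scale models exhibit.  Every reaction carries a
    dedicated pseudo-gene GPR, so synthetic transcriptomes map one-to-one
    onto reactions.  The terminal secretion doubles as the biomass reaction
    for FBA.  Backbone reactions are labelled with glycolysis / citric acid
    cycle subsystems to define the carbon-core scoring subset.
    """
    rng = np.random.default_rng(seed)
    edges: list[tuple[int | None, int | None]] = [(None, 0)]
    for i in range(n_metabolites - 1):
        edges.append((i, i + 1))
    edges.append((n_metabolites - 1, None))
    n_backbone = len(edges)
    while len(edges) < n_backbone + n_extra:
        a, b = (int(x) for x in rng.integers(0, n_metabolites, 2))
        if a != b:
            edges.append((a, b))
    N = len(edges)
    S = np.zeros((n_metabolites, N))
    ids, gprs, subsystems = [], [], []
    lb = np.zeros(N)
    ub = np.full(N, 1000.0)
    half = n_metabolites // 2
    for j, (a, b) in enumerate(edges):
        if a is None:
            rid, sub = "EX_upt", "Exchange"
            ub[j] = uptake_ub
        elif b is None:
            rid, sub = "EX_sec", "Exchange"
        elif j < n_backbone:
            rid = f"B{j:02d}"
            sub = "Glycolysis" if a < half else "Citric acid cycle"
        else:
            rid, sub = f"X{j - n_backbone:02d}", "Other"
        if a is not None:
            S[a, j] -= 1.0
        if b is not None:
            S[b, j] += 1.0
        ids.append(rid)
        gprs.append(f"G_{rid}")
        subsystems.append(sub)
    n_rev = int(round(reversible_frac * n_extra))
    rev_idx = rng.choice(np.arange(n_backbone, N), size=n_rev, replace=False)
    lb[rev_idx] = -1000.0
    return MetabolicNetwork(
        metabolite_ids=[f"M{i}" for i in range(n_metabolites)],
        reaction_ids=ids, S=S, lower_bound=lb, upper_bound=ub,
        gpr_rules=gprs, subsystems=subsystems,
        biomass_reaction="EX_sec",
    )


# ---------------------------------------------------------------------------
# sampling, transcriptome generation, scoring
# ---------------------------------------------------------------------------

def sample_fluxomes(network: MetabolicNetwork, n: int,
                    thinning: int = 100, seed: int = 0) -> pd.DataFrame:
    """Uniform samples from {S v = 0, LB <= v <= UB} via hit-and-run.

    Uses the artificially-centered hit-and-run sampler; deterministic for a
    fixed seed.  Returns an ``n x N`` frame of net fluxes with reaction-id
    columns.

    Raises
    ------
    UnboundedProblemError
        If any bound is infinite (the uniform density does not exist).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (np.all(np.isfinite(network.lower_bound))
            and np.all(np.isfinite(network.upper_bound))):
        raise UnboundedProblemError(
            "polytope has infinite bounds; uniform sampling needs a "
            "bounded polytope"
        )
    if n == 0:
        return pd.DataFrame(columns=network.reaction_ids)
    from cobra.sampling import ACHRSampler

    sampler = ACHRSampler(to_cobra_model(network), thinning=thinning,
                          seed=int(seed))
    samples = sampler.sample(n)
    samples = samples[network.reaction_ids]
    resid = np.abs(network.S @ samples.values.T)
    if resid.max() > 1e-6:
        raise ValidationError(
            f"sampler produced infeasible point (|Sv| = {resid.max():.2e})"
        )
    return samples


def _single_gene(rule: str, rid: str) -> str:
    gene = rule.strip()
    if not gene or " " in gene:
        raise ValidationError(
            f"reaction {rid!r} lacks a one-gene GPR; the synthetic "
            "transcriptome generator requires one gene per reaction"
        )
    return gene


def generate_expression(reference, network: MetabolicNetwork,
                        lambda_frac: float, seed: int = 0,
                        correlated_set: set[str] | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> ExpressionProfile:
    """Synthetic transcriptome for one reference fluxome.

    A fraction ``lambda_frac`` of reactions (chosen at random, or passed in
    as ``correlated_set``) receives expression equal to its absolute net
    flux; all other reactions draw from an exponential distribution whose
    mean equals the mean absolute net flux, so both groups share a scale.
    Values are pushed to gene level through the one-gene-per-reaction GPRs.
    """
    if not 0.0 <= lambda_frac <= 1.0:
        raise ValueError("lambda_frac must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    ref = pd.Series(np.asarray(reference, dtype=float).ravel(),
                    index=network.reaction_ids) \
        if not isinstance(reference, pd.Series) else reference
    n = network.n_reactions
    if correlated_set is None:
        k = int(round(lambda_frac * n))
        chosen = rng.choice(network.reaction_ids, size=k, replace=False)
        correlated_set = set(chosen.tolist())
    mean_flux = float(ref.abs().mean())
    values = {}
    for rid, rule in zip(network.reaction_ids, network.gpr_rules):
        gene = _single_gene(rule, rid)
        if rid in correlated_set:
            values[gene] = abs(float(ref[rid]))
        else:
            values[gene] = float(rng.exponential(mean_flux)) \
                if mean_flux > 0 else float(rng.exponential(1.0))
    return ExpressionProfile(values, sample_id=f"lambda={lambda_frac:g}")


def score_prediction(predicted, reference, subset=None) -> float:
    """Pearson correlation of net fluxes on ``subset`` (default: all
    reactions of the reference).  Returns NaN when either restricted vector
    is constant (correlation undefined)."""
    pred = predicted.net if isinstance(predicted, FluxSolution) else predicted
    if not isinstance(pred, pd.Series):
        pred = pd.Series(np.asarray(pred, dtype=float).ravel(),
                         index=reference.index)
    if subset is None:
        subset = list(reference.index)
    else:
        subset = list(subset)
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    x = pred.loc[subset].to_numpy(dtype=float)
    y = reference.loc[subset].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def core_reaction_set(network: MetabolicNetwork,
                      patterns: tuple[str, ...] = (
                          "glycolysis", "gluconeogenesis",
                          "citric acid", "citrate cycle", "tca"),
                      ) -> list[str]:
    """Carbon-core reactions: subsystem labels matching glycolysis/TCA."""
    out = []
    for rid, sub in zip(network.reaction_ids, network.subsystems):
        low = sub.lower()
        if any(p in low for p in patterns):
            out.append(rid)
    return out


# ---------------------------------------------------------------------------
# the lambda sweep
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBenchmark:
    """One lambda level of the benchmark: reference fluxomes plus their
    generated transcriptomes and the scoring subsets."""

    samples: pd.DataFrame
    lambda_frac: float
    correlated_set: set[str]
    profiles: list[ExpressionProfile]
    core_set: list[str]
    seed: int


def make_benchmark(network: MetabolicNetwork, lambda_frac: float,
                   n: int, seed: int = 0, thinning: int = 100,
                   samples: pd.DataFrame | None = None,
                   core_set: list[str] | None = None) -> SyntheticBenchmark:
    """Sample reference fluxomes (unless given) and generate one synthetic
    transcriptome per sample at the requested ``lambda_frac``."""
    ss = np.random.SeedSequence(seed)
    s_sample, s_select, s_expr = ss.spawn(3)
    if samples is None:
        samples = sample_fluxomes(network, n,
                                  thinning=thinning,
                                  seed=int(s_sample.generate_state(1)[0] %
                                           (2 ** 31)))
    rng_sel = np.random.default_rng(s_select)
    k = int(round(lambda_frac * network.n_reactions))
    correlated = set(rng_sel.choice(network.reaction_ids, size=k,
                                    replace=False).tolist())
    rng_expr = np.random.default_rng(s_expr)
    profiles = [
        generate_expression(samples.iloc[i], network, lambda_frac,
                            correlated_set=correlated, rng=rng_expr)
        for i in range(len(samples))
    ]
    if core_set is None:
        core_set = core_reaction_set(network)
    return SyntheticBenchmark(samples=samples, lambda_frac=lambda_frac,
                              correlated_set=correlated, profiles=profiles,
                              core_set=core_set, seed=seed)


def run_lambda_sweep(network: MetabolicNetwork, lambdas, n_per_lambda: int,
                     methods=("pheflux", "fba_min_l2"), seed: int = 0,
                     thinning: int = 100, V_total: float = 1000.0,
                     epsilon: float = 1e-8,
                     detailed: bool = False):
    """Sweep lambda, scoring each method at carbon-core and genome scale.

    One reference sample set is drawn and shared across all lambda levels,
    so differences between levels are paired and the expression-blind FBA
    baseline is exactly lambda-invariant.  Per-sample solver failures are
    counted (``n_fail``), not fatal.

    Returns
    -------
    DataFrame with columns (lambda, method, scale, mean_r, sd_r, n_ok,
    n_fail); with ``detailed=True`` also the per-sample table
    (lambda, sample, method, scale, r).
    """
    methods = list(methods)
    unknown = set(methods) - {"pheflux", "spot", "fba_min_l2"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    s_sample, *s_lams = ss.spawn(1 + len(lambdas))
    samples = sample_fluxomes(
        network, n_per_lambda, thinning=thinning,
        seed=int(s_sample.generate_state(1)[0] % (2 ** 31)))
    split = split_reversible(network)
    core = core_reaction_set(network)
    scales = [("core", core), ("genome", list(network.reaction_ids))]

    fba_solution = None
    if "fba_min_l2" in methods:
        fba_solution = FBAMinL2(network).fit()

    records = []
    for lam, s_lam in zip(lambdas, s_lams):
        bench = make_benchmark(network, float(lam), n_per_lambda,
                               seed=int(s_lam.generate_state(1)[0] %
                                        (2 ** 31)),
                               samples=samples, core_set=core)
        for i in range(len(samples)):
            reference = samples.iloc[i]
            profile = bench.profiles[i]
            rx = None
            if {"pheflux", "spot"} & set(methods):
                rx = map_expression(split, profile, epsilon=epsilon)
            for method in methods:
                if method == "pheflux":
                    sol = Pheflux(split, rx, V_total=V_total,
                                  epsilon=epsilon).fit()
                elif method == "spot":
                    sol = Spot(split, rx, V_total=V_total).fit()
                else:
                    sol = fba_solution
                ok = sol.ok
                for scale_name, subset in scales:
                    r = score_prediction(sol, reference, subset) \
                        if ok else np.nan
                    records.append({
                        "lambda": float(lam), "sample": i,
                        "method": method, "scale": scale_name,
                        "r": r, "ok": ok,
                    })
    detail = pd.DataFrame(records)
    grouped = detail.groupby(["lambda", "method", "scale"], sort=True)
    agg = grouped.agg(
        mean_r=("r", "mean"), sd_r=("r", "std"),
        n_ok=("ok", "sum"),
        n_fail=("ok", lambda s: int((~s).sum())),
    ).reset_index()
    if detailed:
        return agg, detail
    return agg
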