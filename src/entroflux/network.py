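"""Genome-scale metabolic networks and their irreversible split form.

A constraint-based model is the polytope

    P = { v : S v = 0,  LB <= v <= UB }

where ``S`` is the stoichiometric matrix (metabolites x reactions) and the
bounds encode thermodynamic directionality and measured exchange rates.  All
flux inference in this package runs over the *split* network in which every
reversible reaction is decomposed into a forward and a reverse reaction so
that the flux vector is nonnegative, ``v_i = v_i^f - v_i^r``.

Model files are read through cobrapy (SBML Level 3 + FBC, and the common JSON
model dialect) and converted to a plain :class:`MetabolicNetwork`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ModelFormatError, UnknownReactionError, ValidationError

__all__ = [
    "MetabolicNetwork",
    "SplitNetwork",
    "load_model",
    "split_reversible",
    "apply_medium",
    "read_medium_file",
    "to_cobra_model",
]

#: Default split-flux bounds (mmol/gDW/h) substituted for non-finite bounds.
DEFAULT_BOUNDS = (0.0, 1000.0)


@dataclass
class MetabolicNetwork:
    """A stoichiometric model: the object defining the flux polytope.

    Reactions and metabolites are always referenced by identifier in public
    interfaces; positional indices are an implementation detail.

    Attributes
    ----------
    metabolite_ids : list of str
        Ordered metabolite identifiers (M entries).
    reaction_ids : list of str
        Ordered reaction identifiers (N entries).
    S : ndarray, shape (M, N)
        Stoichiometric coefficients (dimensionless).
    lower_bound, upper_bound : ndarray, shape (N,)
        Flux bounds in mmol/gDW/h.
    gpr_rules : list of str
        Boolean gene-association rule per reaction; empty string when absent.
    subsystems : list of str
        Pathway label per reaction; empty string when absent.
    biomass_reaction : str or None
        Identifier of the biomass (objective) reaction, if any.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    gpr_rules: list[str] = field(default_factory=list)
    subsystems: list[str] = field(default_factory=list)
    biomass_reaction: str | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        if not self.gpr_rules:
            self.gpr_rules = [""] * len(self.reaction_ids)
        if not self.subsystems:
            self.subsystems = [""] * len(self.reaction_ids)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Boolean flag per reaction: can the net flux be negative?"""
        return self.lower_bound < 0

    def validate(self) -> None:
        M, N = len(self.metabolite_ids), len(self.reaction_ids)
        if N == 0:
            raise ValidationError("model declares zero reactions")
        if M == 0:
            raise ValidationError("model declares zero metabolites")
        if self.S.shape != (M, N):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({M}, {N})"
            )
        for arr, name in ((self.lower_bound, "lower_bound"),
                          (self.upper_bound, "upper_bound")):
            if arr.shape != (N,):
                raise ValidationError(f"{name} has length {arr.shape}, expected {N}")
        if np.any(self.lower_bound > self.upper_bound):
            bad = np.flatnonzero(self.lower_bound > self.upper_bound)[0]
            raise ValidationError(
                f"lower_bound > upper_bound for reaction {self.reaction_ids[bad]!r}"
            )
        if len(set(self.reaction_ids)) != N:
            raise ValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != M:
            raise ValidationError("duplicate metabolite identifiers")
        if len(self.gpr_rules) != N or len(self.subsystems) != N:
            raise ValidationError("gpr_rules/subsystems length mismatch")
        if self.biomass_reaction is not None and \
                self.biomass_reaction not in self.reaction_ids:
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise UnknownReactionError(reaction_id) from None

    @property
    def exchange_reactions(self) -> set[str]:
        """Boundary reactions: all stoichiometric coefficients on one side."""
        out = set()
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            nz = col[col != 0]
            if nz.size and (np.all(nz > 0) or np.all(nz < 0)):
                out.add(rid)
        return out

    def copy(self) -> "MetabolicNetwork":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            gpr_rules=list(self.gpr_rules),
            subsystems=list(self.subsystems),
        )


@dataclass
class SplitNetwork:
    """Irreversible decomposition of a :class:`MetabolicNetwork`.

    Every reversible reaction contributes a forward column (equal to the
    original column) and a reverse column (its negation); irreversible
    reactions map to a single column.  All split bounds are nonnegative, so
    the feasible set lives in the positive orthant.
    """

    base: MetabolicNetwork
    split_reaction_ids: list[str]
    S_split: np.ndarray
    lb_split: np.ndarray
    ub_split: np.ndarray
    #: original reaction id -> (forward index, reverse index or None)
    pairing: dict[str, tuple[int, int | None]]

    @property
    def n_split(self) -> int:
        return len(self.split_reaction_ids)

    def net_flux(self, v: np.ndarray) -> np.ndarray:
        """Reconstruct per-original-reaction net fluxes v_f - v_r."""
        v = np.asarray(v, dtype=float)
        net = np.empty(self.base.n_reactions)
        for i, rid in enumerate(self.base.reaction_ids):
            f, r = self.pairing[rid]
            net[i] = v[f] - (v[r] if r is not None else 0.0)
        return net

    def expand_net(self, net: np.ndarray) -> np.ndarray:
        """Lift a net flux vector to nonnegative split coordinates."""
        net = np.asarray(net, dtype=float)
        v = np.zeros(self.n_split)
        for i, rid in enumerate(self.base.reaction_ids):
            f, r = self.pairing[rid]
            if r is None:
                v[f] = net[i]
            else:
                v[f] = max(net[i], 0.0)
                v[r] = max(-net[i], 0.0)
        return v


def split_reversible(network: MetabolicNetwork,
                     default_bounds: tuple[float, float] | None = DEFAULT_BOUNDS,
                     ) -> SplitNetwork:
    """Split reversible reactions into forward/reverse nonnegative pairs.

    Parameters
    ----------
    network : MetabolicNetwork
    default_bounds : (lb, ub) or None
        Substituted for any non-finite bound after splitting, so every split
        flux lives in a finite box (default ``(0, 1000)``).  Finite bounds
        from the model always win.  Pass ``None`` to keep infinities.
    """
    ids, cols, lbs, ubs = [], [], [], []
    pairing: dict[str, tuple[int, int | None]] = {}
    for j, rid in enumerate(network.reaction_ids):
        col = network.S[:, j]
        lb, ub = network.lower_bound[j], network.upper_bound[j]
        fwd = len(ids)
        ids.append(rid)
        cols.append(col)
        lbs.append(max(lb, 0.0))
        ubs.append(max(ub, 0.0))
        if lb < 0:
            rev = len(ids)
            ids.append(rid + "__rev")
            cols.append(-col)
            lbs.append(max(-ub, 0.0))
            ubs.append(-lb)
            pairing[rid] = (fwd, rev)
        else:
            pairing[rid] = (fwd, None)
    lb_split = np.array(lbs)
    ub_split = np.array(ubs)
    if default_bounds is not None:
        lo, hi = default_bounds
        lb_split = np.where(np.isfinite(lb_split), lb_split, lo)
        ub_split = np.where(np.isfinite(ub_split), ub_split, hi)
    return SplitNetwork(
        base=network,
        split_reaction_ids=ids,
        S_split=np.column_stack(cols),
        lb_split=lb_split,
        ub_split=ub_split,
        pairing=pairing,
    )


def apply_medium(network: MetabolicNetwork,
                 uptakes: dict[str, tuple[float, float] | float],
                 ) -> MetabolicNetwork:
    """Return a copy of ``network`` with exchange bounds set from ``uptakes``.

    ``uptakes`` maps reaction id to ``(lb, ub)`` or to a bare lower bound
    (the usual convention for uptake rates, which are negative exchanges).
    Bounds of reactions not mentioned are untouched.
    """
    out = network.copy()
    for rid, bounds in uptakes.items():
        j = out.reaction_index(rid)
        if isinstance(bounds, (int, float)):
            out.lower_bound[j] = float(bounds)
        else:
            lb, ub = bounds
            out.lower_bound[j] = float(lb)
            out.upper_bound[j] = float(ub)
    out.validate()
    return out


def read_medium_file(path) -> dict[str, tuple[float, float] | float]:
    """Read a medium file: ``reaction_id<TAB>lb[<TAB>ub]`` per line."""
    uptakes: dict[str, tuple[float, float] | float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) == 2:
                uptakes[parts[0]] = float(parts[1])
            elif len(parts) == 3:
                uptakes[parts[0]] = (float(parts[1]), float(parts[2]))
            else:
                raise ModelFormatError(
                    f"{path}: line {lineno}: expected 2 or 3 columns"
                )
    return uptakes


# ---------------------------------------------------------------------------
# cobrapy bridge
# ---------------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    if len(model.reactions) == 0:
        raise ValidationError(f"model {model.id!r} declares zero reactions")
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    gprs, subsystems = [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        gprs.append(rxn.gene_reaction_rule or "")
        subsystems.append(rxn.subsystem or "")
    biomass = None
    try:
        coeffs = {r.id: c for r, c in
                  model.objective.expression.as_coefficients_dict().items()
                  if hasattr(r, "id")}
    except Exception:
        coeffs = {}
    for rid in rxn_ids:
        fwd = coeffs.get(rid, 0)
        if fwd:
            biomass = rid
            break
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bound=lb,
        upper_bound=ub,
        gpr_rules=gprs,
        subsystems=subsystems,
        biomass_reaction=biomass,
    )


def to_cobra_model(network: MetabolicNetwork, model_id: str = "entroflux"):
    """Materialize a cobrapy ``Model`` equivalent to ``network``.

    Used for SBML/JSON export and for polytope sampling; infinite bounds are
    preserved (cobra handles them).
    """
    from cobra import Metabolite, Model, Reaction

    model = Model(model_id)
    mets = {mid: Metabolite(mid, compartment="c")
            for mid in network.metabolite_ids}
    rxns = []
    for j, rid in enumerate(network.reaction_ids):
        rxn = Reaction(rid)
        rxn.lower_bound = float(network.lower_bound[j])
        rxn.upper_bound = float(network.upper_bound[j])
        rxn.subsystem = network.subsystems[j]
        stoich = {mets[mid]: network.S[i, j]
                  for i, mid in enumerate(network.metabolite_ids)
                  if network.S[i, j] != 0}
        rxn.add_metabolites(stoich)
        rxns.append(rxn)
    model.add_reactions(rxns)
    # gene_reaction_rule must be set after the reaction joins a model
    for j, rid in enumerate(network.reaction_ids):
        if network.gpr_rules[j]:
            model.reactions.get_by_id(rid).gene_reaction_rule = network.gpr_rules[j]
    if network.biomass_reaction is not None:
        model.objective = network.biomass_reaction
    return model


def load_model(path, dialect: str | None = None) -> MetabolicNetwork:
    """Load an SBML (L3+FBC) or JSON-dialect metabolic model.

    Parameters
    ----------
    path : str or Path
        Model file.
    dialect : {"sbml", "json"}, optional
        Inferred from the file extension when omitted.

    Returns
    -------
    MetabolicNetwork
        Validated network; reactions without a gene association carry an
        empty rule; subsystem labels are preserved verbatim.
    """
    import cobra.io

    path = str(path)
    if dialect is None:
        dialect = "json" if path.endswith(".json") else "sbml"
    if dialect not in ("sbml", "json"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "json":
            model = cobra.io.load_json_model(path)
        else:
            model = cobra.io.read_sbml_model(path)
    except (ValidationError, FileNotFoundError):
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"cannot parse {path!r} as {dialect}: {exc}") from exc
    return _from_cobra(model)
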