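"""Compartmentalized stoichiometric network: schema, validation, JSON and
SBML (Level 3 core) round trip.

JSON schema::

    {"metabolites": [{"id", "name", "compartment"}],
     "reactions": [{"id", "stoich": {met: coef}, "reversible", "lb", "ub",
                    "subsystem", "tags": [...], "exchange_metabolite"}]}

Compartments come from a closed five-element set. Exactly one reaction must
carry the ``atp_demand`` tag (the FBA objective); ``exchange``-tagged
reactions are flagged with the measured metabolite they transport so tissue
concentrations can constrain them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

COMPARTMENTS = frozenset(
    {"extracellular", "cytosol", "mitochondria", "microsome", "lysosome"}
)
KNOWN_TAGS = frozenset({"exchange", "ros_producing", "atp_demand"})


class NetworkSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkSchemaError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: dict[str, float]
    reversible: bool
    lb: float
    ub: float
    subsystem: str
    tags: frozenset[str] = frozenset()
    exchange_metabolite: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", frozenset(self.tags))
        if not self.stoich:
            raise NetworkSchemaError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise NetworkSchemaError(f"reaction {self.id!r}: lb > ub")
        if not self.reversible and self.lb < 0:
            raise NetworkSchemaError(
                f"reaction {self.id!r}: irreversible but lower bound < 0"
            )
        unknown = self.tags - KNOWN_TAGS
        if unknown:
            raise NetworkSchemaError(f"reaction {self.id!r}: unknown tags {sorted(unknown)}")
        if "exchange" in self.tags and not self.exchange_metabolite:
            raise NetworkSchemaError(
                f"reaction {self.id!r}: exchange reactions must name their metabolite"
            )


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise NetworkSchemaError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise NetworkSchemaError("duplicate reaction ids")
        known = set(met_ids)
        for rxn in self.reactions:
            dangling = set(rxn.stoich) - known
            if dangling:
                raise NetworkSchemaError(
                    f"reaction {rxn.id!r} references absent metabolite(s) "
                    f"{sorted(dangling)}"
                )
        demands = [r.id for r in self.reactions if "atp_demand" in r.tags]
        if len(demands) != 1:
            raise NetworkSchemaError(
                f"exactly one ATP-demand reaction required, found {demands}"
            )

    @property
    def atp_demand(self) -> Reaction:
        return next(r for r in self.reactions if "atp_demand" in r.tags)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if "exchange" in r.tags]

    @property
    def subsystems(self) -> list[str]:
        return sorted({r.subsystem for r in self.reactions})

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def exchange_for(self, metabolite_name: str) -> Reaction | None:
        for r in self.exchanges:
            if r.exchange_metabolite == metabolite_name:
                return r
        return None

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus row/column id orders."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[index[met], j] = coef
        return S, met_ids, rxn_ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            sorted(self.metabolites, key=lambda m: m.id)
            == sorted(other.metabolites, key=lambda m: m.id)
            and {r.id: _rxn_key(r) for r in self.reactions}
            == {r.id: _rxn_key(r) for r in other.reactions}
        )


def _rxn_key(r: Reaction):
    return (
        {k: round(v, 9) for k, v in r.stoich.items()},
        r.reversible, round(r.lb, 9), round(r.ub, 9), r.subsystem,
        tuple(sorted(r.tags)), r.exchange_metabolite,
    )


# ---------------------------------------------------------------------------
# JSON

def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "reversible": r.reversible,
                "lb": r.lb,
                "ub": r.ub,
                "subsystem": r.subsystem,
                "tags": sorted(r.tags),
                "exchange_metabolite": r.exchange_metabolite,
            }
            for r in network.reactions
        ],
    }


def network_from_dict(payload: dict) -> MetabolicNetwork:
    try:
        metabolites = [Metabolite(**m) for m in payload["metabolites"]]
        reactions = [
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                reversible=bool(r["reversible"]),
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                subsystem=r.get("subsystem", ""),
                tags=frozenset(r.get("tags", [])),
                exchange_metabolite=r.get("exchange_metabolite"),
            )
            for r in payload["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkSchemaError(f"malformed network payload: {exc}") from exc
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions)


def save_network(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_network(path) -> MetabolicNetwork:
    """Load a network from JSON (or SBML if the suffix is .xml/.sbml)."""
    path = str(path)
    if path.endswith((".xml", ".sbml")):
        return read_sbml(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkSchemaError(f"{path}: invalid JSON: {exc}") from exc
    return network_from_dict(payload)


# ---------------------------------------------------------------------------
# SBML Level 3 core (subset) via cobrapy; schema extras ride in reaction notes

def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("metaboflux")
    mets = {}
    for m in network.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    for r in network.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.add_metabolites({mets[k]: v for k, v in r.stoich.items()})
        cr.notes["subsystem"] = r.subsystem
        cr.notes["tags"] = "|".join(sorted(r.tags)) or "none"
        cr.notes["reversible"] = str(r.reversible)
        if r.exchange_metabolite:
            cr.notes["exchange_metabolite"] = r.exchange_metabolite
        model.add_reactions([cr])
    model.objective = network.atp_demand.id
    return model


def write_sbml(network: MetabolicNetwork, path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(network), str(path))


def read_sbml(path) -> MetabolicNetwork:
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    ]
    reactions = []
    for cr in model.reactions:
        notes = dict(cr.notes)
        tags = notes.get("tags", "none")
        reactions.append(
            Reaction(
                id=cr.id,
                stoich={m.id: float(v) for m, v in cr.metabolites.items()},
                reversible=notes.get("reversible", "False") == "True",
                lb=float(cr.lower_bound),
                ub=float(cr.upper_bound),
                subsystem=notes.get("subsystem", ""),
                tags=frozenset() if tags == "none" else frozenset(tags.split("|")),
                exchange_metabolite=notes.get("exchange_metabolite"),
            )
        )
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions)
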