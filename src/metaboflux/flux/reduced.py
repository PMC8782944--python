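"""Reduced, hand-curated cardiomyocyte metabolic network.

A ~50-reaction stand-in for a genome-scale cardiomyocyte reconstruction:
glucose uptake and glycolysis, glycogen turnover, lactate exchange,
pyruvate and acetate oxidation, a lumped TCA cycle, beta-oxidation of four
phospholipid-derived acyl-CoA species (palmitoyl-, stearoyl-, oleoyl-,
hexadecenoyl-CoA) via microsomal and lysosomal routes, lumped oxidative
phosphorylation with a small stoichiometric ROS by-product, the creatine
kinase shuttle and a cytosolic ATP demand, spread over five compartments.

Endogenous pools (glycogen, phospholipid) are drawn through pseudo-exchange
reactions so measured tissue levels can constrain them like true uptakes.
"""

from __future__ import annotations

from importlib import resources

from .model import MetabolicNetwork, Metabolite, Reaction

_FATTY_ACIDS = {
    # id stem -> (acetyl-CoA per molecule, NADH, FADH2) from beta-oxidation
    "palm": (8, 7, 7),    # C16:0
    "stear": (9, 8, 8),   # C18:0
    "ole": (9, 8, 7),     # C18:1
    "hexd": (8, 7, 6),    # C16:1
}


def _metabolites() -> list[Metabolite]:
    extracellular = ["glc_e", "lac_e", "ac_e", "o2_e", "palm_e", "co2_e"]
    cytosol = [
        "glc_c", "g6p_c", "f16bp_c", "g3p_c", "pyr_c", "lac_c", "ac_c",
        "accoa_c", "atp_c", "adp_c", "nad_c", "nadh_c", "glyc_c",
        "cr_c", "pcr_c", "o2_c", "co2_c",
    ] + [f"{fa}_c" for fa in _FATTY_ACIDS] + [f"{fa}coa_c" for fa in _FATTY_ACIDS]
    mito = [
        "pyr_m", "accoa_m", "nad_m", "nadh_m", "fad_m", "fadh2_m",
        "atp_m", "adp_m", "o2_m", "co2_m", "ros_m",
    ] + [f"{fa}coa_m" for fa in _FATTY_ACIDS]
    out = [Metabolite(m, m, "extracellular") for m in extracellular]
    out += [Metabolite(m, m, "cytosol") for m in cytosol]
    out += [Metabolite(m, m, "mitochondria") for m in mito]
    out.append(Metabolite("pl_r", "phospholipid pool", "microsome"))
    out.append(Metabolite("pl_l", "phospholipid (autophagosomal)", "lysosome"))
    return out


def _rxn(rid, stoich, subsystem, lb=0.0, ub=1000.0, reversible=False,
         tags=(), exchange_metabolite=None) -> Reaction:
    return Reaction(
        id=rid, stoich=stoich, reversible=reversible, lb=lb, ub=ub,
        subsystem=subsystem, tags=frozenset(tags),
        exchange_metabolite=exchange_metabolite,
    )


def reduced_cardiomyocyte_network() -> MetabolicNetwork:
    reactions = [
        # exchanges (import direction positive)
        _rxn("EX_glc", {"glc_e": 1}, "Exchange", ub=10,
             tags=["exchange"], exchange_metabolite="glucose"),
        _rxn("EX_lac", {"lac_e": 1}, "Exchange", lb=-1000, ub=1,
             reversible=True, tags=["exchange"], exchange_metabolite="lactate"),
        _rxn("EX_ac", {"ac_e": 1}, "Exchange", ub=2,
             tags=["exchange"], exchange_metabolite="acetate"),
        _rxn("EX_o2", {"o2_e": 1}, "Exchange", ub=1000,
             tags=["exchange"], exchange_metabolite="oxygen"),
        _rxn("EX_palm", {"palm_e": 1}, "Exchange", ub=1,
             tags=["exchange"], exchange_metabolite="palmitate"),
        _rxn("EX_co2", {"co2_e": 1}, "Exchange", lb=-1000, ub=0,
             reversible=True, tags=["exchange"], exchange_metabolite="co2"),
        # endogenous pool draws
        _rxn("EX_glycogen_pool", {"glyc_c": 1}, "Glycogen metabolism", ub=2,
             tags=["exchange"], exchange_metabolite="glycogen"),
        _rxn("EX_pl_pool", {"pl_r": 1}, "Phospholipid metabolism", ub=1,
             tags=["exchange"], exchange_metabolite="choline"),
        # transport
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, "Transport"),
        _rxn("LACt", {"lac_e": -1, "lac_c": 1}, "Transport",
             lb=-1000, reversible=True),
        _rxn("ACt", {"ac_e": -1, "ac_c": 1}, "Transport"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, "Transport"),
        _rxn("O2tm", {"o2_c": -1, "o2_m": 1}, "Transport"),
        _rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, "Transport"),
        _rxn("CO2tout", {"co2_c": -1, "co2_e": 1}, "Transport"),
        _rxn("PALMt", {"palm_e": -1, "palm_c": 1}, "Transport"),
        _rxn("PYRtm", {"pyr_c": -1, "pyr_m": 1}, "Transport"),
        _rxn("ANT", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1},
             "Transport"),
        _rxn("ACCOAtm", {"accoa_c": -1, "accoa_m": 1}, "Transport"),
        # glycolysis
        _rxn("HK", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
             "Glycolysis"),
        _rxn("PFK", {"g6p_c": -1, "atp_c": -1, "f16bp_c": 1, "adp_c": 1},
             "Glycolysis"),
        _rxn("ALD_TPI", {"f16bp_c": -1, "g3p_c": 2}, "Glycolysis"),
        _rxn("GAPDH_PK",
             {"g3p_c": -1, "adp_c": -2, "nad_c": -1,
              "pyr_c": 1, "atp_c": 2, "nadh_c": 1}, "Glycolysis"),
        # glycogen turnover
        _rxn("GLYS", {"g6p_c": -1, "atp_c": -1, "glyc_c": 1, "adp_c": 1},
             "Glycogen metabolism"),
        _rxn("GLYP", {"glyc_c": -1, "g6p_c": 1}, "Glycogen metabolism"),
        # pyruvate / lactate
        _rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
             "Pyruvate metabolism", lb=-1000, reversible=True),
        _rxn("PDH", {"pyr_m": -1, "nad_m": -1,
                     "accoa_m": 1, "nadh_m": 1, "co2_m": 1},
             "Pyruvate metabolism"),
        # acetate activation
        _rxn("ACS", {"ac_c": -1, "atp_c": -2, "accoa_c": 1, "adp_c": 2},
             "Acetate metabolism"),
        # lumped TCA cycle
        _rxn("TCA", {"accoa_m": -1, "nad_m": -3, "fad_m": -1, "adp_m": -1,
                     "co2_m": 2, "nadh_m": 3, "fadh2_m": 1, "atp_m": 1},
             "TCA cycle"),
        # malate-aspartate shuttle (lumped redox transfer)
        _rxn("MAS", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
             "Redox shuttle"),
        # lumped oxidative phosphorylation with ROS by-product
        _rxn("ETC_NADH", {"nadh_m": -1, "o2_m": -0.5, "adp_m": -2.5,
                          "nad_m": 1, "atp_m": 2.5, "ros_m": 0.005},
             "Oxidative phosphorylation", tags=["ros_producing"]),
        _rxn("ETC_FADH2", {"fadh2_m": -1, "o2_m": -0.5, "adp_m": -1.5,
                           "fad_m": 1, "atp_m": 1.5, "ros_m": 0.005},
             "Oxidative phosphorylation", tags=["ros_producing"]),
        _rxn("ROS_DETOX", {"ros_m": -1}, "ROS detoxification"),
        # phospholipid-derived fatty acids
        _rxn("PLASE_MS",
             {"pl_r": -1, "palm_c": 0.25, "stear_c": 0.25,
              "ole_c": 0.25, "hexd_c": 0.25}, "Phospholipid metabolism"),
        _rxn("AUTOPHAGY", {"pl_r": -1, "pl_l": 1}, "Lysosomal degradation"),
        _rxn("PLASE_LYS",
             {"pl_l": -1, "palm_c": 0.25, "stear_c": 0.25,
              "ole_c": 0.25, "hexd_c": 0.25}, "Lysosomal degradation"),
        # creatine kinase and ATP demand
        _rxn("CK", {"atp_c": -1, "cr_c": -1, "adp_c": 1, "pcr_c": 1},
             "Creatine kinase", lb=-1000, reversible=True),
        _rxn("ATPASE", {"atp_c": -1, "adp_c": 1}, "ATP demand", ub=10000,
             tags=["atp_demand"]),
    ]
    for fa, (n_accoa, n_nadh, n_fadh2) in _FATTY_ACIDS.items():
        reactions += [
            _rxn(f"FACS_{fa}",
                 {f"{fa}_c": -1, "atp_c": -2, f"{fa}coa_c": 1, "adp_c": 2},
                 "Fatty acid oxidation"),
            _rxn(f"CPT_{fa}", {f"{fa}coa_c": -1, f"{fa}coa_m": 1},
                 "Fatty acid oxidation"),
            _rxn(f"BOX_{fa}",
                 {f"{fa}coa_m": -1, "nad_m": -n_nadh, "fad_m": -n_fadh2,
                  "accoa_m": n_accoa, "nadh_m": n_nadh, "fadh2_m": n_fadh2,
                  "ros_m": 0.02},
                 "Fatty acid oxidation", tags=["ros_producing"]),
        ]
    return MetabolicNetwork(metabolites=_metabolites(), reactions=reactions)


def default_network_path():
    """Path of the bundled JSON copy of the reduced network."""
    return resources.files("metaboflux.data") / "reduced_cardiomyocyte.json"
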