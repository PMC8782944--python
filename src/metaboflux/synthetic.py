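"""Seeded synthetic inputs: concentration tables with a two-group,
three-tissue design, raw FIDs with known metabolite content, and toy
metabolic networks for optimizer oracle tests.

Biological variation is log-normal with a configured coefficient of
variation (concentrations are positive and right-skewed); group effects are
multiplicative fold changes on the arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nmr import FID, TSP, TSP_PROTONS, PeakRegion
from .table import ConcentrationTable


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative group effect: treatment mean = fold_change x control mean."""

    metabolite: str
    tissue: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise DesignError(
                f"fold_change for {self.metabolite}/{self.tissue} must be > 0"
            )


@dataclass
class StudyDesign:
    tissues: list[str]
    groups: list[str]  # control first
    n_per_group: dict[str, int]  # tissue -> n
    seed: int
    baseline_means: dict[str, float]
    cv: float
    effects: list[EffectSpec] = field(default_factory=list)
    wet_weight_range: tuple[float, float] = (0.08, 0.12)

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups) or len(self.groups) != 2:
            raise DesignError("need exactly two distinct group labels, control first")
        for tissue in self.tissues:
            n = self.n_per_group.get(tissue)
            if n is None or n < 2:
                raise DesignError(f"n_per_group for {tissue!r} must be >= 2")
        if self.cv <= 0:
            raise DesignError("cv must be > 0")
        bad = [m for m, v in self.baseline_means.items() if v <= 0]
        if bad:
            raise DesignError(f"non-positive baseline means: {bad}")
        for eff in self.effects:
            if eff.metabolite not in self.baseline_means:
                raise DesignError(
                    f"effect references unknown metabolite {eff.metabolite!r}"
                )
            if eff.tissue not in self.tissues:
                raise DesignError(f"effect references unknown tissue {eff.tissue!r}")


@dataclass(frozen=True)
class PeakLibraryEntry:
    metabolite: str
    center_ppm: float
    protons: int
    linewidth_hz: float

    def __post_init__(self) -> None:
        if self.protons < 1:
            raise DesignError(f"{self.metabolite}: protons must be >= 1")
        if self.linewidth_hz <= 0:
            raise DesignError(f"{self.metabolite}: linewidth must be > 0")


# --------------------------------------------------------------------------
# study defaults

TISSUES = ["maternal_heart", "placenta", "fetal_heart"]
GROUPS = ["sham", "rupp"]
N_PER_GROUP = {"maternal_heart": 5, "placenta": 5, "fetal_heart": 4}

#: Baseline tissue concentrations, µmol/g wet weight (glycogen in mobile-1H
#: glucosyl-equivalents). Typical rodent cardiac/placental magnitudes.
BASELINE_MEANS: dict[str, float] = {
    "ATP": 4.0, "ADP": 1.5, "AMP": 0.5, "PCr": 6.0, "creatine": 8.0,
    "NAD": 0.40, "NADH": 0.02,
    "succinate": 0.52, "fumarate": 0.02, "citrate": 0.30, "malate": 0.25,
    "glucose": 2.0, "glycogen": 10.0, "lactate": 5.0, "myo-inositol": 3.0,
    "acetate": 0.5, "acetylcarnitine": 0.6, "carnitine": 1.5,
    "choline": 0.3, "phosphocholine": 0.8,
    "alanine": 1.0, "glycine": 1.0, "valine": 0.3, "leucine": 0.3,
    "isoleucine": 0.15, "glutamate": 5.0, "glutamine": 3.0,
    "aspartate": 1.5, "taurine": 20.0,
}

#: Reported significant directions; only the fetal glucose fold (0.49) has a
#: stated magnitude, all other magnitudes are neutral defaults 1.5 / 0.67.
DEFAULT_EFFECTS: list[EffectSpec] = [
    EffectSpec("NADH", "maternal_heart", 1.5),
    EffectSpec("glucose", "maternal_heart", 1.5),
    EffectSpec("glycogen", "maternal_heart", 1.5),
    EffectSpec("acetate", "maternal_heart", 1.5),
    EffectSpec("acetylcarnitine", "maternal_heart", 1.5),
    EffectSpec("succinate", "maternal_heart", 0.67),
    EffectSpec("aspartate", "maternal_heart", 0.67),
    EffectSpec("ATP", "placenta", 1.5),
    EffectSpec("glycogen", "placenta", 1.5),
    EffectSpec("carnitine", "placenta", 1.5),
    EffectSpec("choline", "placenta", 1.5),
    EffectSpec("phosphocholine", "placenta", 1.5),
    EffectSpec("valine", "placenta", 0.67),
    EffectSpec("glucose", "fetal_heart", 0.49),
    EffectSpec("glycine", "fetal_heart", 0.67),
]


def default_design(seed: int = 0, cv: float = 0.15,
                   effects: list[EffectSpec] | None = None) -> StudyDesign:
    return StudyDesign(
        tissues=list(TISSUES),
        groups=list(GROUPS),
        n_per_group=dict(N_PER_GROUP),
        seed=seed,
        baseline_means=dict(BASELINE_MEANS),
        cv=cv,
        effects=list(DEFAULT_EFFECTS) if effects is None else effects,
    )


# --------------------------------------------------------------------------
# concentration tables

def generate_concentration_table(design: StudyDesign) -> ConcentrationTable:
    """Draw one log-normal concentration per sample x metabolite.

    The log-normal is parametrized so its arithmetic mean equals
    baseline x fold_change and its coefficient of variation equals
    ``design.cv``. Identical seeds yield identical tables.
    """
    rng = np.random.default_rng(design.seed)
    sigma2 = np.log1p(design.cv ** 2)
    sigma = np.sqrt(sigma2)
    fold = {
        (eff.tissue, eff.metabolite): eff.fold_change for eff in design.effects
    }
    metabolites = list(design.baseline_means)
    rows = []
    for tissue in design.tissues:
        for group in design.groups:
            treated = group != design.groups[0]
            for i in range(design.n_per_group[tissue]):
                weight = rng.uniform(*design.wet_weight_range)
                row = {
                    "sample_id": f"{tissue}_{group}_{i + 1}",
                    "tissue": tissue,
                    "group": group,
                    "wet_weight_g": weight,
                }
                for met in metabolites:
                    mean = design.baseline_means[met]
                    if treated:
                        mean *= fold.get((tissue, met), 1.0)
                    mu = np.log(mean) - sigma2 / 2.0
                    row[met] = float(np.exp(rng.normal(mu, sigma)))
                rows.append(row)
    return ConcentrationTable(pd.DataFrame(rows), group_order=list(design.groups))


# --------------------------------------------------------------------------
# FIDs

#: Default peak library: 12 metabolites plus the TSP reference. Shifts are
#: canonical-ish but spaced >= 0.15 ppm so default regions do not overlap;
#: overlap scenarios are opt-in via a custom library.
DEFAULT_PEAK_LIBRARY: list[PeakLibraryEntry] = [
    PeakLibraryEntry(TSP, 0.00, TSP_PROTONS, 1.0),
    PeakLibraryEntry("lactate", 1.33, 3, 1.0),
    PeakLibraryEntry("alanine", 1.48, 3, 1.0),
    PeakLibraryEntry("acetate", 1.92, 3, 1.0),
    PeakLibraryEntry("succinate", 2.41, 4, 1.0),
    PeakLibraryEntry("citrate", 2.66, 4, 1.0),
    PeakLibraryEntry("aspartate", 2.81, 2, 1.0),
    PeakLibraryEntry("creatine", 3.04, 3, 1.0),
    PeakLibraryEntry("choline", 3.21, 9, 1.0),
    PeakLibraryEntry("taurine", 3.43, 2, 1.0),
    PeakLibraryEntry("glucose", 5.23, 1, 1.0),
    PeakLibraryEntry("fumarate", 6.52, 2, 1.0),
    PeakLibraryEntry("ATP", 8.53, 1, 1.0),
]


@dataclass(frozen=True)
class Acquisition:
    """Spectrometer settings; defaults follow a 600 MHz 1D acquisition with
    20 ppm sweep width and 2.6 s acquisition time."""

    sfrq_mhz: float = 600.0
    sweep_ppm: float = 20.0
    aq_s: float = 2.6
    carrier_ppm: float = 4.7

    @property
    def npoints(self) -> int:
        return int(round(self.aq_s * self.sweep_ppm * self.sfrq_mhz))


def generate_fid(
    concentrations: dict[str, float],
    library: list[PeakLibraryEntry] | None = None,
    acquisition: Acquisition | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FID:
    """Sum of decaying complex exponentials, one per library peak.

    Peak amplitude is concentration x protons; frequency comes from the
    chemical shift relative to the carrier; decay rate from the natural
    linewidth (FWHM, Hz). White complex noise of standard deviation
    ``noise_sd`` is added per point. The FID is linear in the
    concentrations at zero noise.
    """
    library = DEFAULT_PEAK_LIBRARY if library is None else library
    acq = acquisition or Acquisition()
    if noise_sd < 0:
        raise DesignError("noise_sd must be >= 0")
    names = {entry.metabolite for entry in library}
    if TSP not in names or TSP not in concentrations:
        raise DesignError("TSP must be present in both library and concentrations")
    tsp_entry = next(e for e in library if e.metabolite == TSP)
    if abs(tsp_entry.center_ppm) > 1e-12:
        raise DesignError("TSP library entry must sit at 0 ppm")

    n = acq.npoints
    t = np.arange(n) * (acq.aq_s / n)
    fid = np.zeros(n, dtype=complex)
    for entry in library:
        conc = concentrations.get(entry.metabolite, 0.0)
        if conc == 0.0:
            continue
        if conc < 0:
            raise DesignError(f"negative concentration for {entry.metabolite}")
        amplitude = conc * entry.protons
        f_hz = (entry.center_ppm - acq.carrier_ppm) * acq.sfrq_mhz
        fid += amplitude * np.exp((2j * np.pi * f_hz - np.pi * entry.linewidth_hz) * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + rng.normal(0, noise_sd, n) + 1j * rng.normal(0, noise_sd, n)
    return FID(points=fid, sfrq_mhz=acq.sfrq_mhz, sweep_ppm=acq.sweep_ppm,
               aq_s=acq.aq_s, carrier_ppm=acq.carrier_ppm)


def regions_for_library(
    library: list[PeakLibraryEntry] | None = None,
    half_width_ppm: float = 0.03,
    glycogen: set[str] = frozenset({"glycogen"}),
) -> list[PeakRegion]:
    """Integration regions centred on each library peak (TSP included)."""
    library = DEFAULT_PEAK_LIBRARY if library is None else library
    return [
        PeakRegion(
            metabolite=e.metabolite,
            ppm_low=round(e.center_ppm - half_width_ppm, 6),
            ppm_high=round(e.center_ppm + half_width_ppm, 6),
            protons=e.protons,
            is_glycogen=e.metabolite in glycogen,
        )
        for e in library
    ]


# --------------------------------------------------------------------------
# toy metabolic networks

def generate_toy_network(kind: str):
    """Tiny fixtures for optimizer tests.

    ``chain``    uptake -> conversion (2 ATP / substrate) -> ATP demand.
    ``branched`` two conversion routes with ATP yields 2 and 3.
    ``blocked``  ATP demand whose only producing reaction lacks a substrate
                 source, forcing a zero optimum.
    """
    from .flux.model import MetabolicNetwork, Metabolite, Reaction

    def met(mid: str) -> Metabolite:
        return Metabolite(id=mid, name=mid, compartment="cytosol")

    uptake = Reaction(
        id="uptake", stoich={"s": 1.0}, reversible=False, lb=0.0, ub=10.0,
        subsystem="Exchange", tags=frozenset({"exchange"}),
        exchange_metabolite="substrate",
    )
    demand = Reaction(
        id="atp_demand", stoich={"atp": -1.0, "adp": 1.0}, reversible=False,
        lb=0.0, ub=1000.0, subsystem="ATP demand",
        tags=frozenset({"atp_demand"}),
    )
    if kind == "chain":
        mets = [met("s"), met("atp"), met("adp")]
        conv = Reaction(
            id="conv", stoich={"s": -1.0, "adp": -2.0, "atp": 2.0},
            reversible=False, lb=0.0, ub=1000.0, subsystem="Conversion",
        )
        reactions = [uptake, conv, demand]
    elif kind == "branched":
        mets = [met("s"), met("atp"), met("adp")]
        low = Reaction(
            id="conv_low", stoich={"s": -1.0, "adp": -2.0, "atp": 2.0},
            reversible=False, lb=0.0, ub=1000.0, subsystem="Conversion",
        )
        high = Reaction(
            id="conv_high", stoich={"s": -1.0, "adp": -3.0, "atp": 3.0},
            reversible=False, lb=0.0, ub=1000.0, subsystem="Conversion",
        )
        reactions = [uptake, low, high, demand]
    elif kind == "blocked":
        mets = [met("s"), met("x"), met("atp"), met("adp")]
        conv = Reaction(
            id="conv", stoich={"x": -1.0, "adp": -2.0, "atp": 2.0},
            reversible=False, lb=0.0, ub=1000.0, subsystem="Conversion",
        )
        reactions = [uptake, conv, demand]
    else:
        raise DesignError(f"unknown toy network kind {kind!r}")
    return MetabolicNetwork(metabolites=mets, reactions=reactions)
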