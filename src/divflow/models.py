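"""Demographic model descriptions for a two-population divergence history.

All quantities are in standard coalescent (diffusion) units:

* time is measured in units of ``2 * N_ref`` generations,
* population sizes ``nu`` are ratios ``N / N_ref``,
* migration rates ``M_ij = 2 * N_ref * m_ij`` where ``m_ij`` is the
  per-generation fraction of population *i* replaced by migrants from
  population *j*.

The ancestral population size is fixed at ``nu = 1``, i.e. ``N_ref`` is the
size of the population ancestral to the split.  The model ladder runs from
strict isolation (SI) to secondary contact with asymmetric migration and an
optional post-contact size change in either daughter population.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence


class Scenario(str, enum.Enum):
    """Two-population divergence scenarios, ordered by complexity."""

    SI = "SI"                            # strict isolation
    IM_SYM = "IM_SYM"                    # continuous symmetric migration
    SC_SYM = "SC_SYM"                    # secondary contact, symmetric
    SC_ASYM = "SC_ASYM"                  # secondary contact, asymmetric
    SC_ASYM_GROWTH1 = "SC_ASYM_GROWTH1"  # + size change in population 1
    SC_ASYM_GROWTH2 = "SC_ASYM_GROWTH2"  # + size change in population 2


#: Free parameter names, in optimisation order, for each scenario.
FREE_PARAMS: dict[Scenario, tuple[str, ...]] = {
    Scenario.SI: ("nu1", "nu2", "t_iso"),
    Scenario.IM_SYM: ("nu1", "nu2", "t_sc", "m_sym"),
    Scenario.SC_SYM: ("nu1", "nu2", "t_iso", "t_sc", "m_sym"),
    Scenario.SC_ASYM: ("nu1", "nu2", "t_iso", "t_sc", "m12", "m21"),
    Scenario.SC_ASYM_GROWTH1: ("nu1", "nu2", "t_iso", "t_sc", "m12", "m21", "nu1_0"),
    Scenario.SC_ASYM_GROWTH2: ("nu1", "nu2", "t_iso", "t_sc", "m12", "m21", "nu2_0"),
}


@dataclass(frozen=True)
class DemographicModel:
    """A concrete two-population history in coalescent units.

    Parameters
    ----------
    scenario
        Which member of the model ladder this parameterisation belongs to.
    nu1, nu2
        Sizes of populations 1 and 2 relative to ``N_ref`` during the
        isolation epoch (and, absent a growth parameter, to the present).
    t_iso
        Duration of the migration-free epoch that follows the split.
    t_sc
        Duration of the contact epoch, which ends at the present.
    m12, m21
        Scaled migration rates ``2 N_ref m`` during the contact epoch.
        ``m12`` is migration *into* population 1 from population 2
        (forward in time).
    nu1_0, nu2_0
        Present-day relative sizes during the contact epoch for the growth
        variants; ``None`` means "same as nu1/nu2".
    """

    scenario: Scenario
    nu1: float
    nu2: float
    t_iso: float
    t_sc: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    nu1_0: float | None = None
    nu2_0: float | None = None

    def __post_init__(self) -> None:
        s = Scenario(self.scenario)
        object.__setattr__(self, "scenario", s)
        for name in ("nu1", "nu2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("t_iso", "t_sc", "m12", "m21"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.t_div <= 0:
            raise ValueError("total divergence time t_iso + t_sc must be > 0")
        if s is Scenario.SI and (self.m12 != 0 or self.m21 != 0 or self.t_sc != 0):
            raise ValueError("SI requires m12 = m21 = 0 and t_sc = 0")
        if s in (Scenario.IM_SYM, Scenario.SC_SYM) and self.m12 != self.m21:
            raise ValueError(f"{s.value} requires m12 == m21")
        if s is Scenario.IM_SYM and self.t_iso != 0:
            raise ValueError("IM_SYM has migration since the split (t_iso = 0)")
        for name in ("nu1_0", "nu2_0"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def t_div(self) -> float:
        """Total time since the split, in units of 2*N_ref generations."""
        return self.t_iso + self.t_sc

    @property
    def contact_sizes(self) -> tuple[float, float]:
        """Relative population sizes during the contact epoch."""
        s1 = self.nu1 if self.nu1_0 is None else self.nu1_0
        s2 = self.nu2 if self.nu2_0 is None else self.nu2_0
        return s1, s2

    @property
    def free_params(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.scenario]

    def param_vector(self) -> list[float]:
        """Free parameters as a flat vector (optimisation order)."""
        out = []
        for name in self.free_params:
            if name == "m_sym":
                out.append(self.m12)
            else:
                out.append(getattr(self, name))
        return out

    def with_params(self, values: Sequence[float]) -> "DemographicModel":
        """Rebuild the model from a flat free-parameter vector."""
        names = self.free_params
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(values)}")
        kw: dict[str, float] = {}
        for name, v in zip(names, values):
            if name == "m_sym":
                kw["m12"] = v
                kw["m21"] = v
            else:
                kw[name] = float(v)
        return replace(self, **kw)

    @classmethod
    def from_params(cls, scenario: Scenario | str, values: Sequence[float]) -> "DemographicModel":
        """Build a model of ``scenario`` from a flat free-parameter vector."""
        template = _TEMPLATES[Scenario(scenario)]
        return template.with_params(values)


_TEMPLATES = {
    Scenario.SI: DemographicModel(Scenario.SI, 1, 1, 1.0),
    Scenario.IM_SYM: DemographicModel(Scenario.IM_SYM, 1, 1, 0.0, 1.0, 1.0, 1.0),
    Scenario.SC_SYM: DemographicModel(Scenario.SC_SYM, 1, 1, 1.0, 0.5, 1.0, 1.0),
    Scenario.SC_ASYM: DemographicModel(Scenario.SC_ASYM, 1, 1, 1.0, 0.5, 1.0, 0.5),
    Scenario.SC_ASYM_GROWTH1: DemographicModel(
        Scenario.SC_ASYM_GROWTH1, 1, 1, 1.0, 0.5, 1.0, 0.5, nu1_0=1.0
    ),
    Scenario.SC_ASYM_GROWTH2: DemographicModel(
        Scenario.SC_ASYM_GROWTH2, 1, 1, 1.0, 0.5, 1.0, 0.5, nu2_0=1.0
    ),
}


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes drawn from each population.

    The study design is 9 diploid individuals per taxon, i.e. ``n1 = n2 = 18``
    haploid genomes.
    """

    n1: int = 18
    n2: int = 18

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("haploid sample sizes must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class ConversionConstants:
    """Constants linking coalescent units to absolute units.

    Attributes
    ----------
    mu
        Mutation rate per nucleotide per generation.
    gen_time
        Generation time in years.
    L_eff
        Effective (callable) sequence length behind the SFS, in nucleotides;
        anchors ``theta = 4 * N_ref * mu * L_eff``.
    """

    mu: float = 1e-9
    gen_time: float = 2.0
    L_eff: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu", "gen_time", "L_eff"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class ConvertedParams:
    """Demographic parameters in absolute units (individuals and years)."""

    N_ref: float
    N1: float
    N2: float
    T_div_years: float
    T_sc_years: float
    m12: float
    m21: float

    def as_dict(self) -> dict[str, float]:
        return {
            "N_ref": self.N_ref,
            "N1": self.N1,
            "N2": self.N2,
            "T_div_years": self.T_div_years,
            "T_sc_years": self.T_sc_years,
            "m12": self.m12,
            "m21": self.m21,
        }
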