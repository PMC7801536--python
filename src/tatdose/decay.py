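"""Embedded nuclear decay data for the nuclides used in targeted
radionuclide therapy studies with this package: F-18, the At-211 chain,
I-131 and Lu-177.

Emission inventories (per-decay yields and energies) are compiled from
published ICRP-107-style decay tables and shipped as a human-readable JSON
file (``data/nuclides.json``).  Continuous beta spectra are represented by
their mean energy for dose bookkeeping; the spectrum endpoint is stored
alongside so that the microdosimetric sampler can draw from an
allowed-shape spectrum.

Tally convention: alpha particles feed the "alpha dose" component;
electrons, positrons and photons (through their secondary electrons) all
feed the "beta dose" component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .constants import LN2

#: Emission kinds contributing to the alpha dose component.
ALPHA_KINDS = frozenset({"alpha"})
#: Emission kinds contributing to the beta dose component (photons are
#: counted through their secondary electrons, i.e. as beta dose).
BETA_KINDS = frozenset({"beta_plus", "beta_minus", "discrete_electron", "photon"})

VALID_KINDS = ALPHA_KINDS | BETA_KINDS

#: Daughters with half-lives longer than this are dropped from flattened
#: inventories by default (e.g. 31.6-year Bi-207 after an At-211 alpha decay:
#: negligible during treatment-relevant times).
DEFAULT_TRUNCATION_H = 24.0


class UnsupportedNuclideError(KeyError):
    """Raised when a nuclide name is not in the embedded decay table."""


@dataclass(frozen=True)
class EmissionLine:
    """A single per-decay emission.

    energy is the line energy in MeV (mean energy for continuous beta
    spectra); yield_ is the number of emissions per parent decay;
    endpoint is the beta-spectrum endpoint in MeV when known.
    """

    kind: str
    energy: float
    yield_: float
    endpoint: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown emission kind {self.kind!r}")
        if not self.energy > 0:
            raise ValueError("emission energy must be positive")
        if not self.yield_ > 0:
            raise ValueError("emission yield must be positive")

    @property
    def component(self) -> str:
        """Dose component this line feeds: 'alpha' or 'beta'."""
        return "alpha" if self.kind in ALPHA_KINDS else "beta"


@dataclass(frozen=True)
class Nuclide:
    name: str
    half_life: Optional[float]  # hours; None for a stable nuclide
    emissions: tuple[EmissionLine, ...] = ()
    daughters: tuple[tuple["Nuclide", float], ...] = ()

    def __post_init__(self) -> None:
        if self.half_life is not None and not self.half_life > 0:
            raise ValueError("half-life must be positive")
        total = sum(b for _, b in self.daughters)
        if self.daughters and not 0 < total <= 1 + 1e-9:
            raise ValueError("branching fractions must lie in (0, 1] and sum to <= 1")

    @property
    def stable(self) -> bool:
        return self.half_life is None


@dataclass
class ChainInventory:
    """Flattened per-parent-decay emission inventory of a decay chain."""

    parent: str
    lines: tuple[EmissionLine, ...]
    truncation_half_life: float
    #: (name, half_life_h, cumulative branching) of daughters dropped because
    #: their half-life exceeds the truncation (or they are stable).
    dropped: list[tuple[str, Optional[float], float]] = field(default_factory=list)

    def per_decay_energy(self, component: Optional[str] = None) -> float:
        """Total emitted energy per parent decay in MeV, optionally for one
        dose component ('alpha' or 'beta')."""
        return sum(
            ln.energy * ln.yield_
            for ln in self.lines
            if component is None or ln.component == component
        )

    def component_lines(self, component: str) -> tuple[EmissionLine, ...]:
        return tuple(ln for ln in self.lines if ln.component == component)


def _load_table() -> dict:
    with resources.files("tatdose.data").joinpath("nuclides.json").open() as fh:
        return json.load(fh)


_TABLE_CACHE: Optional[dict] = None


def _table() -> dict:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = _load_table()
    return _TABLE_CACHE


def load_nuclide(name: str) -> Nuclide:
    """Load a nuclide (with its recursively resolved daughters) from the
    embedded decay table.

    Raises UnsupportedNuclideError for names outside the table.
    """
    table = _table()
    if name not in table or name.startswith("_"):
        supported = sorted(k for k in table if not k.startswith("_"))
        raise UnsupportedNuclideError(
            f"nuclide {name!r} is not in the embedded decay table; "
            f"supported: {supported}"
        )
    entry = table[name]
    emissions = tuple(
        EmissionLine(
            kind=e["kind"],
            energy=e["energy_mev"],
            yield_=e["yield"],
            endpoint=e.get("endpoint_mev"),
        )
        for e in entry["emissions"]
    )
    daughters = tuple(
        (load_nuclide(d["name"]), d["branching"]) for d in entry["daughters"]
    )
    return Nuclide(
        name=name,
        half_life=entry["half_life_h"],
        emissions=emissions,
        daughters=daughters,
    )


def physical_lambda(nuclide: Nuclide) -> float:
    """Physical decay constant lambda_phy = ln(2)/half_life, in 1/h."""
    if nuclide.half_life is None:
        return 0.0
    return LN2 / nuclide.half_life


def chain_inventory(
    nuclide: Nuclide, truncation_half_life: float = DEFAULT_TRUNCATION_H
) -> ChainInventory:
    """Flatten a decay chain into a per-parent-decay emission inventory.

    Daughters with half-life <= truncation_half_life are assumed to decay
    in transient equilibrium with the parent (instantaneous on the time
    scale of interest); their emissions are folded in scaled by the
    cumulative branching fraction.  Longer-lived (or stable) daughters are
    dropped and reported in ``dropped``.
    """
    if not truncation_half_life > 0:
        raise ValueError("truncation half-life must be positive")

    lines: list[EmissionLine] = []
    dropped: list[tuple[str, Optional[float], float]] = []

    def visit(nuc: Nuclide, branching: float) -> None:
        for ln in nuc.emissions:
            lines.append(
                EmissionLine(
                    kind=ln.kind,
                    energy=ln.energy,
                    yield_=ln.yield_ * branching,
                    endpoint=ln.endpoint,
                )
            )
        for child, frac in nuc.daughters:
            cumulative = branching * frac
            if child.stable or child.half_life > truncation_half_life:
                if child.emissions or not child.stable:
                    dropped.append((child.name, child.half_life, cumulative))
                continue
            visit(child, cumulative)

    visit(nuclide, 1.0)
    return ChainInventory(
        parent=nuclide.name,
        lines=tuple(lines),
        truncation_half_life=truncation_half_life,
        dropped=dropped,
    )


def inventory_as_nuclide(inv: ChainInventory, half_life: float) -> Nuclide:
    """Re-wrap a flattened inventory as a daughter-free nuclide (useful for
    idempotence checks and for feeding samplers that expect a Nuclide)."""
    return Nuclide(name=inv.parent, half_life=half_life, emissions=inv.lines)
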