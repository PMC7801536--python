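"""Microdosimetric kinetic model: absorbed dose -> cell survival ->
EQDX(alpha/beta), per voxel and per volume of interest.

The surviving fraction in an arbitrary radiation field delivering dose D is

    S(D) = exp[-(alpha0 + beta z*_1D) D - G beta D^2]

where z*_1D is the saturation-corrected dose-mean specific energy of the
field's lineal-energy spectrum, alpha0 = alpha - beta z*_1D,ref removes the
reference radiation's microdosimetric contribution from the measured
linear coefficient, and G is a Lea-Catcheside-type dose-protraction factor.
For a mono-exponential dose rate with decay constant lambda_phy +
lambda_bio and first-order sublesion repair at rate mu,

    G = (lambda_phy + lambda_bio) / (mu + lambda_phy + lambda_bio).

The equieffective dose of a reference treatment with fraction size X is

    EQDX = -ln(S) / (alpha + beta X),

and a VOI's EQDX uses the mass-weighted mean surviving fraction
S_VOI = sum_i S_i m_i / sum_i m_i (equivalent-uniform-dose-style
aggregation), for which the dose-mass histogram is the key summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .microspec import DomainGeometry, LinealSpectrum, z_star_1d

__all__ = [
    "MKMParams",
    "recovery_factor",
    "survival",
    "eqdx",
    "rbe_limit_ratio",
    "voi_survival",
    "eqdx_map",
    "dmh",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class MKMParams:
    """Radiobiological parameters of the reference cell line / treatment.

    Defaults are HSG-cell linear-quadratic parameters with a 2 Gy reference
    fraction (EQD2 with alpha/beta = 4.08) and the fixed MKM domain
    (r_d = 0.282 um, y0 = 93.4 keV/um).  z_star_ref (Gy) is the
    saturation-corrected dose-mean specific energy of the reference
    radiation, from which alpha0 = alpha - beta * z_star_ref is derived.
    """

    alpha: float = 0.251  # Gy^-1
    beta: float = 0.0615  # Gy^-2
    mu: float = 1.5  # h^-1, sublesion recovery rate
    X: float = 2.0  # Gy, reference fraction size
    geom: DomainGeometry = field(default_factory=DomainGeometry)
    z_star_ref: float = 0.0  # Gy

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "X"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mu < 0:
            raise ValueError("recovery rate mu must be nonnegative")
        if self.z_star_ref < 0:
            raise ValueError("z_star_ref must be nonnegative")
        if self.alpha0 < 0:
            warnings.warn(
                "alpha0 = alpha - beta*z_star_ref is negative; check z_star_ref",
                stacklevel=2,
            )

    @property
    def alpha0(self) -> float:
        """Linear coefficient in the limit LET -> 0: alpha - beta*z_star_ref."""
        return self.alpha - self.beta * self.z_star_ref

    @property
    def alpha_beta_ratio(self) -> float:
        return self.alpha / self.beta

    @property
    def reference_slope(self) -> float:
        """alpha + beta*X, the EQDX denominator (Gy^-1)."""
        return self.alpha + self.beta * self.X

    # -- parameter file round trip ------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "mu": self.mu,
                    "X": self.X,
                    "r_d": self.geom.r_d,
                    "y0": self.geom.y0,
                    "z_star_ref": self.z_star_ref,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MKMParams":
        raw = json.loads(Path(path).read_text())
        defaults = cls()
        geom = DomainGeometry(
            r_d=raw.get("r_d", defaults.geom.r_d),
            y0=raw.get("y0", defaults.geom.y0),
        )
        return cls(
            alpha=raw.get("alpha", defaults.alpha),
            beta=raw.get("beta", defaults.beta),
            mu=raw.get("mu", defaults.mu),
            X=raw.get("X", defaults.X),
            geom=geom,
            z_star_ref=raw.get("z_star_ref", defaults.z_star_ref),
        )

    def with_reference(self, z_star_ref: float) -> "MKMParams":
        return replace(self, z_star_ref=z_star_ref)


def recovery_factor(lambda_phy: float, lambda_bio, mu: float):
    """Dose-protraction factor G in (0, 1] for a mono-exponential dose
    rate: G = lambda_eff / (mu + lambda_eff) with lambda_eff = lambda_phy +
    lambda_bio (all in 1/h).  mu = 0 recovers the acute-exposure limit
    G = 1; lambda -> infinity likewise."""
    lam = lambda_phy + np.asarray(lambda_bio, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("total decay constant lambda_phy + lambda_bio must be > 0")
    if mu < 0:
        raise ValueError("recovery rate mu must be nonnegative")
    g = lam / (mu + lam)
    return float(g) if g.ndim == 0 else g


def survival(dose, z_star, g, p: MKMParams, underflow_counter: Optional[dict] = None):
    """Surviving fraction S = exp(-(alpha0 + beta z*) D - G beta D^2).

    Underflowing survivals are clamped at the smallest positive double;
    pass a dict as underflow_counter to count clamped voxels.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    expo = -(p.alpha0 + p.beta * np.asarray(z_star)) * d - np.asarray(g) * p.beta * d**2
    with np.errstate(under="ignore"):
        s = np.exp(expo)
    clamped = s < _TINY
    if underflow_counter is not None:
        underflow_counter["survival_underflow"] = underflow_counter.get(
            "survival_underflow", 0
        ) + int(np.count_nonzero(clamped))
    s = np.where(clamped, _TINY, s)
    return float(s) if s.ndim == 0 else s


def eqdx(s, p: MKMParams):
    """Equieffective dose EQDX = -ln(S) / (alpha + beta X), Gy."""
    sa = np.asarray(s, dtype=float)
    if np.any(sa <= 0) or np.any(sa > 1):
        raise ValueError("surviving fraction must lie in (0, 1]")
    out = -np.log(sa) / p.reference_slope
    return float(out) if out.ndim == 0 else out


def rbe_limit_ratio(z_star: float, p: MKMParams) -> float:
    """Low-dose limit of EQDX/D: (alpha0 + beta z*_1D) / (alpha + beta X).

    Equals RBE at D -> 0 multiplied by alpha/(alpha + beta X); for the
    reference radiation itself (z* = z*_ref) it is alpha/(alpha + beta X).
    """
    return (p.alpha0 + p.beta * z_star) / p.reference_slope


def voi_survival(s, mass, dose=None, dose_floor: float = 1e-9) -> float:
    """Mass-weighted mean surviving fraction of a VOI:
    S_VOI = sum S_i m_i / sum m_i.

    If per-voxel doses are given, voxels below dose_floor (Gy) are
    excluded (they carry S ~ 1 and numerically meaningless exponentials
    for fields that never irradiated them)."""
    s = np.asarray(s, dtype=float).ravel()
    m = np.asarray(mass, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("empty VOI")
    if s.shape != m.shape:
        raise ValueError("survival and mass arrays must match")
    if np.any(m <= 0):
        raise ValueError("voxel masses must be positive")
    if dose is not None:
        keep = np.asarray(dose, dtype=float).ravel() >= dose_floor
        if keep.any():
            s, m = s[keep], m[keep]
    return float(np.sum(s * m) / np.sum(m))


def eqdx_map(
    dose_alpha: np.ndarray,
    dose_beta: np.ndarray,
    spec_alpha: Optional[LinealSpectrum],
    spec_beta: Optional[LinealSpectrum],
    p: MKMParams,
    lambda_phy: float,
    lambda_bio: Optional[np.ndarray] = None,
    counters: Optional[dict] = None,
) -> np.ndarray:
    """Per-voxel EQDX map.

    Each voxel's lineal-energy spectrum is the dose-weighted mixture of the
    nuclide's alpha and beta component spectra (the mixing is linear, so
    z*_1D mixes as (D_a z*_a + D_b z*_b)/(D_a + D_b)); G uses the voxel's
    own lambda_phy + lambda_bio.  Voxels with zero total dose get EQDX 0.
    """
    da = np.asarray(dose_alpha, dtype=float)
    db = np.asarray(dose_beta, dtype=float)
    if da.shape != db.shape:
        raise ValueError("dose map shapes differ")
    if lambda_bio is not None and np.shape(lambda_bio) != da.shape:
        raise ValueError("lambda_bio map shape differs from dose maps")
    if spec_alpha is None and np.any(da > 0):
        raise ValueError("alpha dose present but no alpha spectrum supplied")
    if spec_beta is None and np.any(db > 0):
        raise ValueError("beta dose present but no beta spectrum supplied")

    za = z_star_1d(spec_alpha, p.geom) if spec_alpha is not None else 0.0
    zb = z_star_1d(spec_beta, p.geom) if spec_beta is not None else 0.0
    total = da + db
    with np.errstate(invalid="ignore", divide="ignore"):
        z_mix = np.where(total > 0, (da * za + db * zb) / np.where(total > 0, total, 1.0), 0.0)
    lam_bio = np.zeros_like(da) if lambda_bio is None else np.asarray(lambda_bio, dtype=float)
    g = recovery_factor(lambda_phy, lam_bio, p.mu)
    s = survival(total, z_mix, g, p, underflow_counter=counters)
    out = np.where(total > 0, -np.log(np.clip(s, _TINY, 1.0)) / p.reference_slope, 0.0)
    return out


def dmh(dose, mass, bin_edges) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-mass histogram: for each dose edge d, the fraction
    of VOI mass receiving dose >= d.  Returns (edges, mass fraction);
    monotone nonincreasing with DMH(0) = 1."""
    d = np.asarray(dose, dtype=float).ravel()
    m = np.asarray(mass, dtype=float).ravel()
    edges = np.asarray(bin_edges, dtype=float)
    if d.size == 0:
        raise ValueError("empty VOI")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    total = m.sum()
    frac = np.array([m[d >= e].sum() / total for e in edges])
    return edges, frac


def dmh_to_csv(edges: np.ndarray, frac: np.ndarray, path: str | Path) -> None:
    arr = np.column_stack([edges, frac])
    np.savetxt(
        path, arr, delimiter=",", header="dose_gy,cumulative_mass_fraction", comments=""
    )
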