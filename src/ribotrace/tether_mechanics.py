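"""Worm-like-chain mechanics of the bead--DNA--protein--ribosome dumbbell.

The tether in a passive-mode optical-tweezers experiment is a series
assembly: two optical traps, two double-stranded DNA handles, and the
unstructured polypeptide outside the ribosomal exit tunnel.  Every element
carries the same force, and the total end-to-end distance is fixed while
the traps are stationary.  This module converts between force, extension,
polypeptide contour length and amino-acid counts under that force balance.

Polymer models
--------------
* Unstructured polypeptide: inextensible worm-like chain (WLC) in the
  Marko--Siggia interpolation,

      F = (kBT / P) * [ 1 / (4 (1 - x/L)^2) - 1/4 + x/L ],

  with persistence length ``P = 0.6`` nm and a contour conversion of
  0.365 nm per amino acid.
* DNA handles: extensible WLC, the same interpolation with the enthalpic
  substitution ``x/L -> x/L - F/S`` (stretch modulus ``S = 1200`` pN,
  persistence length 35 nm).
* Traps: Hookean, two springs of 0.25 pN/nm acting in series on the
  dumbbell, i.e. an effective stiffness of 0.125 pN/nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WLCParams", "TetherModel", "MechanicalState",
    "wlc_force", "wlc_extension", "ewlc_extension",
    "aa_to_contour", "contour_to_aa",
    "total_extension", "series_compliance", "equilibrium_force",
    "force_trace_to_aa", "detection_resolution",
    "DEFAULT_MODEL",
]

#: thermal energy at 25 degrees C, pN nm
KBT_25C = 4.11

#: rise per base pair of B-form DNA, nm
NM_PER_BP = 0.338

_FORCE_TOL = 1e-10  # pN, root-find tolerance on the force balance


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters of one polymer segment.

    ``stretch_modulus=None`` selects the inextensible chain (used for the
    polypeptide); a finite value adds the enthalpic term (DNA handles).
    """

    persistence_length: float  # nm
    contour_length: float      # nm
    stretch_modulus: float | None = None  # pN, None = inextensible

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.contour_length < 0:
            raise ValueError("contour_length must be >= 0")
        if self.stretch_modulus is not None and self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0 when finite")


@dataclass(frozen=True)
class TetherModel:
    """Geometry, elasticity and physical constants of the full dumbbell.

    Defaults describe the standard construct: two 2-kb DNA handles
    (4000 bp total at 0.338 nm/bp), a 0.6 nm persistence-length
    polypeptide at 0.365 nm per amino acid, two 0.25 pN/nm traps in
    series, and 40 residues sequestered in the ribosomal exit tunnel.
    """

    dna: WLCParams = field(default_factory=lambda: WLCParams(
        persistence_length=35.0, contour_length=4000 * NM_PER_BP,
        stretch_modulus=1200.0))
    protein_persistence: float = 0.6     # nm
    nm_per_aa: float = 0.365             # nm per amino acid
    trap_stiffness_each: float = 0.25    # pN/nm
    n_traps_in_series: int = 2
    kBT: float = KBT_25C                 # pN nm
    tunnel_occupancy: int = 40           # aa sequestered in the exit tunnel

    def __post_init__(self) -> None:
        if self.nm_per_aa <= 0:
            raise ValueError("nm_per_aa must be > 0")
        if self.trap_stiffness_each <= 0:
            raise ValueError("trap_stiffness_each must be > 0")
        if not 0 <= self.tunnel_occupancy <= 50:
            raise ValueError("tunnel_occupancy must be in [0, 50]")

    @property
    def trap_stiffness_effective(self) -> float:
        """Series combination of the trap springs, pN/nm."""
        return self.trap_stiffness_each / self.n_traps_in_series

    def protein_params(self, contour_length: float) -> WLCParams:
        return WLCParams(self.protein_persistence, contour_length)


DEFAULT_MODEL = TetherModel()


@dataclass(frozen=True)
class MechanicalState:
    """Solved force-balance state of the series tether at one instant."""

    force: float              # pN, common to all series elements
    protein_contour: float    # nm, out-of-tunnel polypeptide contour
    dna_extension: float      # nm
    protein_extension: float  # nm
    trap_displacement: float  # nm, summed over both traps

    @property
    def total_extension(self) -> float:
        return self.dna_extension + self.protein_extension + self.trap_displacement


# ---------------------------------------------------------------------------
# single-segment force/extension relations
# ---------------------------------------------------------------------------

def _marko_siggia(z):
    """Dimensionless Marko--Siggia force, F*P/kBT as a function of x/L."""
    return 1.0 / (4.0 * (1.0 - z) ** 2) - 0.25 + z


def _marko_siggia_deriv(z):
    return 1.0 / (2.0 * (1.0 - z) ** 3) + 1.0


def _marko_siggia_inverse(phi: float) -> float:
    """Solve _marko_siggia(z) = phi for z in [0, 1)."""
    if phi <= 0:
        return 0.0
    return brentq(lambda z: _marko_siggia(z) - phi, 0.0, 1.0 - 1e-14,
                  xtol=1e-14, rtol=8.9e-16)


def wlc_force(extension_fraction, params: WLCParams, kBT: float = KBT_25C):
    """Force of an inextensible WLC at fractional extension ``x/L``.

    Diverges as the fraction approaches 1; fractions >= 1 are a domain
    error.  Accepts scalars or arrays.
    """
    z = np.asarray(extension_fraction, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("extension_fraction must lie in [0, 1)")
    out = (kBT / params.persistence_length) * _marko_siggia(z)
    return float(out) if np.isscalar(extension_fraction) else out


def wlc_extension(force: float, params: WLCParams, kBT: float = KBT_25C) -> float:
    """Extension (nm) of an inextensible WLC at a given force (pN)."""
    if force < 0:
        raise ValueError("force must be >= 0")
    phi = force * params.persistence_length / kBT
    return params.contour_length * _marko_siggia_inverse(phi)


def ewlc_extension(force: float, params: WLCParams, kBT: float = KBT_25C) -> float:
    """Extension (nm) of an extensible WLC at a given force (pN).

    Solves the Marko--Siggia interpolation with the enthalpic substitution
    x/L -> x/L - F/S; may exceed the contour length at high force.  With
    ``stretch_modulus=None`` this reduces to the inextensible inversion.
    """
    if force <= 0:
        if force == 0:
            return 0.0
        raise ValueError("force must be > 0")
    phi = force * params.persistence_length / kBT
    z = _marko_siggia_inverse(phi)
    if params.stretch_modulus is None:
        return params.contour_length * z
    return params.contour_length * (z + force / params.stretch_modulus)


def _segment_compliance(force: float, params: WLCParams, kBT: float) -> float:
    """Analytic dx/dF (nm/pN) of one WLC segment at the given force."""
    if params.contour_length == 0:
        return 0.0
    phi = force * params.persistence_length / kBT
    z = _marko_siggia_inverse(phi)
    dFdz = (kBT / params.persistence_length) * _marko_siggia_deriv(z)
    comp = params.contour_length / dFdz
    if params.stretch_modulus is not None:
        comp += params.contour_length / params.stretch_modulus
    return comp


# ---------------------------------------------------------------------------
# contour <-> amino acid conversions
# ---------------------------------------------------------------------------

def aa_to_contour(n_aa, nm_per_aa: float = 0.365):
    """Contour length (nm) of ``n_aa`` amino acids."""
    n = np.asarray(n_aa, dtype=float)
    if np.any(n < 0):
        raise ValueError("amino-acid count must be >= 0")
    out = n * nm_per_aa
    return float(out) if np.isscalar(n_aa) else out


def contour_to_aa(contour_nm, nm_per_aa: float = 0.365):
    """Amino-acid count corresponding to a contour length (nm)."""
    length = np.asarray(contour_nm, dtype=float)
    if np.any(length < 0):
        raise ValueError("contour length must be >= 0")
    out = length / nm_per_aa
    return float(out) if np.isscalar(contour_nm) else out


# ---------------------------------------------------------------------------
# series force balance
# ---------------------------------------------------------------------------

def total_extension(model: TetherModel, force: float,
                    protein_contour: float) -> float:
    """Total end-to-end distance (nm) of traps + DNA + protein at ``force``."""
    x = force / model.trap_stiffness_effective
    x += ewlc_extension(force, model.dna, model.kBT)
    if protein_contour > 0:
        x += wlc_extension(force, model.protein_params(protein_contour), model.kBT)
    return x


def solve_state(model: TetherModel, force: float,
                protein_contour: float) -> MechanicalState:
    """Assemble the per-element extensions at a common force."""
    x_prot = (wlc_extension(force, model.protein_params(protein_contour), model.kBT)
              if protein_contour > 0 else 0.0)
    return MechanicalState(
        force=force,
        protein_contour=protein_contour,
        dna_extension=ewlc_extension(force, model.dna, model.kBT),
        protein_extension=x_prot,
        trap_displacement=force / model.trap_stiffness_effective,
    )


def series_compliance(model: TetherModel, force: float,
                      protein_contour: float) -> float:
    """Analytic compliance (nm/pN) of the series tether at ``force``."""
    comp = 1.0 / model.trap_stiffness_effective
    comp += _segment_compliance(force, model.dna, model.kBT)
    if protein_contour > 0:
        comp += _segment_compliance(
            force, model.protein_params(protein_contour), model.kBT)
    return comp


def _solve_force_at_separation(model: TetherModel, separation: float,
                               protein_contour: float,
                               f_hi: float = 60.0) -> float:
    """Force at which the series tether spans ``separation`` nm."""
    f_lo = 1e-9
    if total_extension(model, f_lo, protein_contour) > separation:
        raise ArithmeticError(
            f"force balance has no positive-force solution at separation "
            f"{separation:.3f} nm with protein contour {protein_contour:.3f} nm")
    while total_extension(model, f_hi, protein_contour) < separation:
        f_hi *= 2.0
        if f_hi > 1e5:
            raise ArithmeticError(
                "force balance did not bracket: separation "
                f"{separation:.3f} nm, protein contour {protein_contour:.3f} nm")
    return brentq(
        lambda f: total_extension(model, f, protein_contour) - separation,
        f_lo, f_hi, xtol=_FORCE_TOL)


def equilibrium_force(model: TetherModel, reference_force: float,
                      reference_protein_contour: float,
                      delta_contour: float) -> float:
    """Force after adding ``delta_contour`` nm of polypeptide at fixed traps.

    The reference state (``reference_force``, ``reference_protein_contour``)
    fixes the total trap separation; the returned force re-balances the
    series tether after the protein contour changes.  Adding contour
    (elongation) lowers the force; removing contour (folding) raises it.
    """
    if reference_force <= 0:
        raise ValueError("reference_force must be > 0")
    if reference_protein_contour < 0:
        raise ValueError("reference_protein_contour must be >= 0")
    if delta_contour == 0.0:
        return reference_force
    new_contour = reference_protein_contour + delta_contour
    if new_contour < 0:
        raise ValueError("resulting protein contour would be negative")
    separation = total_extension(model, reference_force,
                                 reference_protein_contour)
    return _solve_force_at_separation(model, separation, new_contour,
                                      f_hi=max(60.0, 4 * reference_force))


class ForceToContourTable:
    """Tabulated inverse of the force balance at fixed trap separation.

    Pre-computes force as a function of out-of-tunnel protein contour on a
    dense grid and inverts it by monotone interpolation; matches a direct
    root solve to better than 1e-6 nm-equivalent over the table range.
    """

    def __init__(self, model: TetherModel, separation: float,
                 contour_max: float, n_grid: int = 512):
        grid = np.linspace(0.0, contour_max, n_grid)
        forces = np.array([
            _solve_force_at_separation(model, separation, lc) for lc in grid])
        # force decreases monotonically with added contour
        self._force_desc = forces[::-1]
        self._contour_desc = grid[::-1]
        self.force_min = forces[-1]
        self.force_max = forces[0]

    def contour(self, force):
        """Protein contour (nm) producing ``force`` at this separation."""
        return np.interp(np.asarray(force, dtype=float),
                         self._force_desc, self._contour_desc)


def _unfolded_level(force: np.ndarray, block: int = 10,
                    split_pN: float = 0.15, n_iter: int = 50) -> float:
    """Unfolded (lowest) force level of a possibly hopping segment.

    Block-averages the segment and separates it into two levels by a 1-D
    two-means split; if the levels differ by more than ``split_pN`` the
    segment is hopping and the lower level is returned, otherwise the
    overall mean.
    """
    m = force.size // block
    v = force[:m * block].reshape(m, block).mean(axis=1) if m >= 2 else force
    lo, hi = float(v.min()), float(v.max())
    for _ in range(n_iter):
        thr = 0.5 * (lo + hi)
        below, above = v[v <= thr], v[v > thr]
        if below.size == 0 or above.size == 0:
            break
        lo_new, hi_new = float(below.mean()), float(above.mean())
        if lo_new == lo and hi_new == hi:
            break
        lo, hi = lo_new, hi_new
    return lo if hi - lo > split_pN else float(v.mean())


def force_trace_to_aa(trace, model: TetherModel, endpoint_codon: int,
                      anchor_seconds: float = 10.0,
                      out_of_tunnel_at_end: float | None = None,
                      n_grid: int = 512) -> np.ndarray:
    """Convert a translation force trace to codon-position series.

    The end of the record is used as an internal length reference: the
    unfolded force level over the last ``anchor_seconds`` (robust to the
    endpoint hopping of the folded C domain) is assigned to
    ``endpoint_codon`` and earlier positions are back-calculated from the
    force balance, so the constant-tunnel-occupancy assumption enters only
    through the endpoint anchoring.

    ``out_of_tunnel_at_end`` is the polypeptide length (aa) outside the
    exit tunnel at the endpoint; by default ``endpoint_codon`` minus the
    model's tunnel occupancy.  Samples with non-positive force are outside
    WLC validity and are flagged as NaN rather than dropped.

    Returns an array of codon positions, same length as the trace.
    """
    force = np.asarray(trace.force, dtype=float)
    bad = force <= 0
    if bad.all():
        raise ValueError("trace contains no positive forces")
    if out_of_tunnel_at_end is None:
        out_of_tunnel_at_end = endpoint_codon - model.tunnel_occupancy
    if out_of_tunnel_at_end <= 0:
        raise ValueError("endpoint chain length outside the tunnel must be > 0")
    n_anchor = max(1, int(round(anchor_seconds * trace.fs)))
    f_end = _unfolded_level(force[~bad][-n_anchor:])
    contour_end = aa_to_contour(out_of_tunnel_at_end, model.nm_per_aa)
    separation = total_extension(model, f_end, contour_end)
    table = ForceToContourTable(model, separation,
                                contour_max=1.15 * contour_end + 10.0,
                                n_grid=n_grid)
    aa = np.full(force.shape, np.nan)
    ok = ~bad
    clipped = np.clip(force[ok], table.force_min, table.force_max)
    aa_out = contour_to_aa(table.contour(clipped), model.nm_per_aa)
    # shift out-of-tunnel count to codon position via the endpoint anchor
    aa[ok] = aa_out + (endpoint_codon - out_of_tunnel_at_end)
    return aa


def detection_resolution(noise_sd: float, fs_native: float, fs_down: float,
                         per_step_signal: float, snr_target: float
                         ) -> tuple[int, float]:
    """Smallest detectable elongation step count and dwell after downsampling.

    White instrument noise of ``noise_sd`` (pN, measured at ``fs_native``)
    scales as sqrt(fs_down/fs_native) when the data are downsampled;
    ``min_steps`` is the smallest number of single-amino-acid steps (each of
    ``per_step_signal`` pN) whose summed signal reaches ``snr_target`` times
    the downsampled noise, and ``min_dwell`` is the time resolution 1/fs_down.
    """
    if min(noise_sd, fs_native, fs_down, per_step_signal, snr_target) <= 0:
        raise ValueError("all inputs must be > 0")
    if fs_down > fs_native:
        raise ValueError("fs_down must not exceed fs_native")
    noise_down = noise_sd * math.sqrt(fs_down / fs_native)
    min_steps = max(1, math.ceil(snr_target * noise_down / per_step_signal
                                 - 1e-9))
    return min_steps, 1.0 / fs_down
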