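"""Lumped-element equivalence of the applicator dielectric layer.

The electrode of a capacitive interstitial applicator forms a cylindrical
capacitor with the surrounding tissue through its thin insulating coating.
Resolving a 30 um coating on a voxel grid is expensive, so the cylindrical
electrode/dielectric shells are replaced by concentric cuboid shells with
much thicker walls.  Replacing the layer changes its capacitance per unit
length, which is restored exactly by assigning the thickened layer an
adapted permittivity eps' chosen so that the layer capacitance is preserved.
Because the coating capacitance dominates the applicator-tissue coupling,
the exterior field of the simplified applicator then matches the detailed
one.

All geometric arguments are accepted in millimetres and converted to SI
internally; capacitances are returned in farad, impedances in ohm.
"""

from __future__ import annotations

import math

MM = 1e-3


def _check_pair(outer: float, inner: float, what: str) -> None:
    if inner <= 0 or outer <= inner:
        raise ValueError(f"{what}: need outer > inner > 0, got {outer} / {inner}")


def coaxial_impedance(
    d0_mm: float, di_mm: float, l_mm: float, sigma: float, eps: float, omega: float
) -> complex:
    """Impedance of the annular layer between two concentric cylindrical conductors.

    Z = ln(d0/di) / (2*pi*l*(sigma + j*omega*eps))

    Parameters
    ----------
    d0_mm, di_mm : float
        Outer and inner diameter of the layer (mm).
    l_mm : float
        Axial length of the layer (mm).
    sigma : float
        Layer conductivity (S/m).
    eps : float
        Layer absolute permittivity (F/m).
    omega : float
        Angular frequency (rad/s).
    """
    _check_pair(d0_mm, di_mm, "coaxial_impedance")
    if l_mm <= 0:
        raise ValueError("coaxial_impedance: length must be > 0")
    kappa = sigma + 1j * omega * eps
    if kappa == 0:
        raise ValueError("coaxial_impedance: sigma and omega*eps are both zero")
    return math.log(d0_mm / di_mm) / (2.0 * math.pi * l_mm * MM * kappa)


def coaxial_capacitance(d0_mm: float, di_mm: float, l_mm: float, eps: float) -> float:
    """Capacitance C = 2*pi*eps*l / ln(d0/di) of a coaxial cylindrical layer (F)."""
    _check_pair(d0_mm, di_mm, "coaxial_capacitance")
    if l_mm <= 0:
        raise ValueError("coaxial_capacitance: length must be > 0")
    if eps <= 0:
        raise ValueError("coaxial_capacitance: permittivity must be > 0")
    return 2.0 * math.pi * eps * l_mm * MM / math.log(d0_mm / di_mm)


def cuboid_capacitance(a_o_mm: float, a_i_mm: float, l_mm: float, eps: float) -> float:
    """Capacitance C = 4*eps*l / ln(a_o/a_i) of a square-annulus (cuboid shell) layer (F).

    ``a_o`` and ``a_i`` are the outer and inner edge lengths of the square
    cross-section.  The form is the cuboid analogue of the coaxial formula
    and, like it, depends only on the edge ratio.
    """
    _check_pair(a_o_mm, a_i_mm, "cuboid_capacitance")
    if l_mm <= 0:
        raise ValueError("cuboid_capacitance: length must be > 0")
    if eps <= 0:
        raise ValueError("cuboid_capacitance: permittivity must be > 0")
    return 4.0 * eps * l_mm * MM / math.log(a_o_mm / a_i_mm)


def equivalent_permittivity(
    eps: float, a_o_mm: float, a_i_mm: float, a_o_prime_mm: float, a_i_prime_mm: float
) -> float:
    """Adapted permittivity preserving the layer capacitance under edge rescaling.

    eps' = eps * ln(a_o'/a_i') / ln(a_o/a_i)

    so that ``cuboid_capacitance(a_o', a_i', l, eps') ==
    cuboid_capacitance(a_o, a_i, l, eps)`` holds identically for every
    length ``l``.  A thicker simplified layer (larger edge ratio) therefore
    gets a proportionally larger permittivity.
    """
    _check_pair(a_o_mm, a_i_mm, "equivalent_permittivity (original edges)")
    _check_pair(a_o_prime_mm, a_i_prime_mm, "equivalent_permittivity (new edges)")
    return eps * math.log(a_o_prime_mm / a_i_prime_mm) / math.log(a_o_mm / a_i_mm)


def surface_equivalent_edge(diameter_mm: float) -> float:
    """Edge length of the square cylinder with the same lateral surface as a circular one.

    Equal lateral surface at equal length means 4*a = pi*d, i.e. a = pi*d/4.
    Used to derive the (un-thickened) cuboid shell edges from the cylindrical
    electrode and coating diameters.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter_mm / 4.0


def adapted_permittivity_for_layer(
    eps: float,
    inner_diameter_mm: float,
    outer_diameter_mm: float,
    a_i_prime_mm: float,
    a_o_prime_mm: float,
    reference: str = "cuboid",
) -> float:
    """Adapted permittivity for a thickened cuboid replacement of a cylindrical layer.

    ``reference`` selects what the thickened layer's capacitance is matched
    to: ``"cuboid"`` (default) matches the equal-surface cuboid shell derived
    from the cylindrical diameters; ``"coaxial"`` matches the cylindrical
    layer capacitance directly.
    """
    if reference == "cuboid":
        a_i = surface_equivalent_edge(inner_diameter_mm)
        a_o = surface_equivalent_edge(outer_diameter_mm)
        return equivalent_permittivity(eps, a_o, a_i, a_o_prime_mm, a_i_prime_mm)
    if reference == "coaxial":
        # match C_coax = 2*pi*eps*l/ln(d0/di) with C_cuboid = 4*eps'*l/ln(a_o'/a_i')
        _check_pair(outer_diameter_mm, inner_diameter_mm, "adapted_permittivity (diameters)")
        _check_pair(a_o_prime_mm, a_i_prime_mm, "adapted_permittivity (new edges)")
        return (
            eps
            * (math.pi / 2.0)
            * math.log(a_o_prime_mm / a_i_prime_mm)
            / math.log(outer_diameter_mm / inner_diameter_mm)
        )
    raise ValueError(f"unknown reference {reference!r} (expected 'cuboid' or 'coaxial')")


def equivalence_report(spec, frequency: float, dielectric) -> dict:
    """Lumped-element summary (Z, C, eps') for an applicator spec.

    ``spec`` is an :class:`~thermoplan.applicators.ApplicatorSpec`;
    ``dielectric`` the coating material.  Returns a JSON-serialisable dict.
    """
    omega = 2.0 * math.pi * frequency
    z = coaxial_impedance(
        spec.dielectric_od, spec.electrode_od, spec.electrode_length,
        dielectric.sigma, dielectric.eps, omega,
    )
    c_coax = coaxial_capacitance(
        spec.dielectric_od, spec.electrode_od, spec.electrode_length, dielectric.eps
    )
    eps_prime = spec.adapted_permittivity(dielectric.eps)
    return {
        "frequency_hz": frequency,
        "coating_impedance_ohm": {"re": z.real, "im": z.imag},
        "coating_capacitance_f": c_coax,
        "adapted_permittivity_f_per_m": eps_prime,
        "adapted_relative_permittivity": eps_prime / (dielectric.eps / dielectric.eps_r),
        "simplified_dielectric_edges_mm": [spec.simplified_dielectric_inner, spec.simplified_dielectric_outer],
        "simplified_electrode_edges_mm": [spec.simplified_electrode_inner, spec.simplified_electrode_outer],
    }
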