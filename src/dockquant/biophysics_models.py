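"""Back-of-envelope biophysics for reconstituted SNARE fusion sites.

Three small calculators accompany the imaging pipeline:

* :func:`copy_number` — how many protein copies a vesicle carries given the
  reconstitution protein:lipid ratio and the vesicle size.
* :func:`bridging_span` — the maximal membrane separation a partially zippered
  SNAREpin can bridge, from the contour length of its unfolded segments.
* :func:`excluded` — whether a protein complex of given diameter is sterically
  excluded from the intermembrane space at a given membrane separation.

All lengths are in nm, concentrations in molar.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

__all__ = [
    "ReconstitutionSpec",
    "ZipperingSpec",
    "ComplexGeometry",
    "SNAREPIN_CPX",
    "SNAREPIN_CPX_SYT1_SYT1",
    "copy_number",
    "bridging_span",
    "excluded",
]

#: Contour length of an extended polypeptide chain, nm per residue.
CONTOUR_PER_RESIDUE = 0.365

#: Headgroup area of a phospholipid in a bilayer, nm^2.
AREA_PER_LIPID = 0.65


@dataclass(frozen=True)
class ReconstitutionSpec:
    """Protein/lipid mix used to form proteoliposomes.

    ``outward_fraction`` is the fraction of reconstituted copies whose
    functional domain faces outward; detergent-mediated reconstitution
    inserts proteins in both orientations, so the default is 0.5.
    """

    protein_concentration: float  # molar
    lipid_concentration: float    # molar
    vesicle_diameter: float = 80.0  # nm
    area_per_lipid: float = AREA_PER_LIPID  # nm^2
    outward_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.protein_concentration < 0:
            raise ValueError("protein_concentration must be >= 0")
        for name in ("lipid_concentration", "vesicle_diameter", "area_per_lipid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.outward_fraction <= 1:
            raise ValueError("outward_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ZipperingSpec:
    """Unfolded-chain accounting for a partially zippered SNAREpin.

    ``unfolded_residues_v`` / ``unfolded_residues_t`` count the residues of
    the v- and t-SNARE that remain as extended chain between the folded
    bundle and the respective membrane anchor; ``folded_offset`` adds any
    rigid contribution of the folded portion along the docking axis.
    """

    unfolded_residues_v: int
    unfolded_residues_t: int
    contour_per_residue: float = CONTOUR_PER_RESIDUE  # nm
    folded_offset: float = 0.0  # nm

    def __post_init__(self) -> None:
        if self.unfolded_residues_v < 0 or self.unfolded_residues_t < 0:
            raise ValueError("residue counts must be >= 0")
        if self.contour_per_residue <= 0:
            raise ValueError("contour_per_residue must be > 0")


@dataclass(frozen=True)
class ComplexGeometry:
    """A prefusion protein complex approximated by its widest diameter."""

    name: str
    diameter: float  # nm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")


#: SNAREpin bound by Complexin, measured across the four-helix bundle + Cpx.
SNAREPIN_CPX = ComplexGeometry("SNAREpin-CpxII", 3.0)
#: SNAREpin flanked on both sides by a Syt1 C2B domain.
SNAREPIN_CPX_SYT1_SYT1 = ComplexGeometry("SNAREpin-CpxII-Syt1-Syt1", 8.0)


def lipid_count(spec: ReconstitutionSpec) -> float:
    """Number of lipids forming the vesicle surface at ``vesicle_diameter``.

    Single-surface counting: the sphere area pi*d^2 divided by the headgroup
    area, i.e. the outer leaflet at the quoted diameter stands in for the
    whole bilayer.  This convention, together with ``area_per_lipid`` 0.65
    nm^2, reproduces the copy numbers quoted for the reconstitution used
    here; both knobs are exposed on the spec.
    """
    return math.pi * spec.vesicle_diameter**2 / spec.area_per_lipid


def copy_number(spec: ReconstitutionSpec) -> tuple[float, int]:
    """Total and outward-facing protein copies per vesicle.

    The protein:lipid mole ratio of the reconstitution mix is assumed to
    carry over to each vesicle, so ``total = lipids * (c_protein/c_lipid)``;
    the outward-facing count is ``round(total * outward_fraction)``.

    Returns
    -------
    (total, outward)
        ``total`` as a float, ``outward`` rounded to the nearest integer.
    """
    total = lipid_count(spec) * spec.protein_concentration / spec.lipid_concentration
    outward = int(round(total * spec.outward_fraction))
    return total, outward


def bridging_span(spec: ZipperingSpec) -> float:
    """Maximal membrane separation bridged by a partially zippered SNAREpin.

    The unfolded v- and t-SNARE segments are treated as fully extended
    chains at ``contour_per_residue`` nm per residue, laid end to end along
    the docking axis; an upper bound, since a real chain with its short
    persistence length will not reach full extension.
    """
    n = spec.unfolded_residues_v + spec.unfolded_residues_t
    return n * spec.contour_per_residue + spec.folded_offset


def excluded(complex_geometry: ComplexGeometry, separation: float) -> bool:
    """Is the complex sterically excluded from the intermembrane space?

    True iff ``separation < diameter`` (strict); at separation exactly equal
    to the complex diameter the complex is taken to just fit.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    return separation < complex_geometry.diameter
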