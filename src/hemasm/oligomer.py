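"""Mass and oxygen-binding-site bookkeeping for hemocyanin oligomers.

Molluscan hemocyanin decamers are rings of ten subunits; each subunit is a
string of functional units carrying one binuclear copper oxygen-binding site
apiece.  Decamers stack into didecamers and multidecamers, and cerithioid
mega-hemocyanin is a tridecamer whose central decamer is built from 12-FU
(~550 kDa) subunits.  This module does the resulting arithmetic: total mass,
total binding sites, and the extra mass contributed by the His/Asp-rich FU-g
insertion of the Muricidae H2 subunits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .protein import FUAnnotation, InsertionCall, ProteinRecord, molecular_weight


@dataclass(frozen=True)
class SubunitSpec:
    label: str
    fu_count: int
    subunit_mass_kda: float
    insert_mass_kda: float = 0.0

    def __post_init__(self) -> None:
        if self.fu_count < 1:
            raise ValueError("fu_count must be >= 1")
        if self.subunit_mass_kda < 0 or self.insert_mass_kda < 0:
            raise ValueError("masses must be >= 0")


SUBUNITS_PER_DECAMER = 10


@dataclass(frozen=True)
class OligomerSpec:
    """(subunit type, number of decamers) pairs; each decamer has 10 subunits."""

    decamers: tuple[tuple[SubunitSpec, int], ...] = ()

    def __post_init__(self) -> None:
        for _sub, count in self.decamers:
            if count < 0:
                raise ValueError("decamer count must be >= 0")


@dataclass
class MassReport:
    total_mass_kda: float
    total_binding_sites: int
    extra_mass_kda: float
    per_decamer: list[dict] = field(default_factory=list)

    def rounded(self) -> dict:
        """Report masses at 0.1-kDa precision (the customary print precision)."""
        return {
            "total_mass_kda": round(self.total_mass_kda, 1),
            "total_binding_sites": self.total_binding_sites,
            "extra_mass_kda": round(self.extra_mass_kda, 1),
        }


def count_binding_sites(oligomer: OligomerSpec) -> int:
    """One oxygen-binding site per FU per subunit, summed over all decamers."""
    return sum(
        count * SUBUNITS_PER_DECAMER * sub.fu_count for sub, count in oligomer.decamers
    )


def total_mass(oligomer: OligomerSpec) -> float:
    return sum(
        count * SUBUNITS_PER_DECAMER * sub.subunit_mass_kda for sub, count in oligomer.decamers
    )


def extra_mass(oligomer: OligomerSpec) -> float:
    """Aggregate insertion (extra) mass over all subunits, in kDa."""
    return sum(
        count * SUBUNITS_PER_DECAMER * sub.insert_mass_kda for sub, count in oligomer.decamers
    )


def mass_report(oligomer: OligomerSpec) -> MassReport:
    per_decamer = [
        {
            "subunit": sub.label,
            "n_decamers": count,
            "mass_kda": count * SUBUNITS_PER_DECAMER * sub.subunit_mass_kda,
            "binding_sites": count * SUBUNITS_PER_DECAMER * sub.fu_count,
            "extra_mass_kda": count * SUBUNITS_PER_DECAMER * sub.insert_mass_kda,
        }
        for sub, count in oligomer.decamers
    ]
    return MassReport(
        total_mass_kda=total_mass(oligomer),
        total_binding_sites=count_binding_sites(oligomer),
        extra_mass_kda=extra_mass(oligomer),
        per_decamer=per_decamer,
    )


def homomeric(sub: SubunitSpec, n_decamers: int) -> OligomerSpec:
    """An oligomer of ``n_decamers`` identical decamers (2 = didecamer)."""
    if n_decamers == 0:
        return OligomerSpec()
    return OligomerSpec(decamers=((sub, n_decamers),))


def build_from_protein(
    protein: ProteinRecord,
    inserts: list[InsertionCall],
    annotation: FUAnnotation,
    n_decamers: int,
) -> OligomerSpec:
    """Bridge sequence-level characterization into oligomer bookkeeping.

    Subunit mass comes from the deduced primary structure, insert mass from
    the insertion calls, and the FU count from the annotation.
    """
    if annotation is None or not annotation.segments:
        raise ValueError("protein lacks an FU annotation")
    sub = SubunitSpec(
        label=protein.id,
        fu_count=len(annotation.segments),
        subunit_mass_kda=molecular_weight(protein) / 1000.0,
        insert_mass_kda=sum(call.mass_da for call in inserts) / 1000.0,
    )
    return homomeric(sub, n_decamers)
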