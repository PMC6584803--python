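"""Epitope footprints and binding stoichiometry.

A footprint is the set of channel residues whose residue-level interaction
probability with a given antibody exceeds a cutoff (>55% by default).  For a
hexameric channel bound by two antibodies, the stoichiometry summary counts
the distinct protomers engaged per antibody, the protomers shared by both
footprints, and whether the two footprints are related by the diametric
(3-position cyclic) symmetry of the hexamer — the operational reading of
"symmetric relative to the axis of the channel pore".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from hexitope.contact_analysis import ContactTable, ResRef
from hexitope.errors import HexitopeError, LookupFailure
from hexitope.struct_io import Topology


@dataclass
class EpitopeFootprint:
    """Channel residues contacted by one antibody above a probability cutoff."""

    antibody: str
    #: (protomer, residue number) -> probability %
    residues: dict[ResRef, float]
    cutoff: float
    inclusive: bool = False
    names: dict[ResRef, str] = field(default_factory=dict)

    @property
    def protomers(self) -> set[str]:
        return {entity for entity, _ in self.residues}

    def by_protomer(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for entity, resnum in sorted(self.residues):
            out.setdefault(entity, []).append(resnum)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "antibody": self.antibody,
                "protomer": entity,
                "residue": self.names.get((entity, num), ""),
                "number": num,
                "probability_pct": round(prob, 1),
            }
            for (entity, num), prob in sorted(self.residues.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class StoichiometrySummary:
    n_antibodies: int
    protomers_per_antibody: dict[str, int]
    shared_protomers: set[str]
    symmetric: bool

    def describe(self) -> str:
        lines = [f"antibodies with non-empty footprint: {self.n_antibodies}"]
        for ab, count in sorted(self.protomers_per_antibody.items()):
            lines.append(f"  {ab}: {count} protomer(s)")
        shared = ", ".join(sorted(self.shared_protomers)) or "none"
        lines.append(f"shared protomers: {shared}")
        lines.append(f"diametrically symmetric: {self.symmetric}")
        return "\n".join(lines)


def _is_protomer(entity: str) -> bool:
    return entity.startswith("P") and entity[1:].isdigit()


def extract_footprint(
    table: ContactTable,
    cutoff: float = 55.0,
    inclusive: bool = False,
) -> dict[str, EpitopeFootprint]:
    """One footprint per antibody from residue-level probabilities.

    Channel residues (entities ``P1``…) are attributed to the antibody whose
    pairs produced the probability (the partner key of the residue-level
    entry); a residue contacted by both antibodies appears in both
    footprints.  The cutoff comparison is strictly greater by default;
    ``inclusive=True`` switches to greater-or-equal.
    """
    if not 0.0 <= cutoff <= 100.0:
        raise HexitopeError(f"cutoff must be in [0, 100], got {cutoff}")
    footprints: dict[str, EpitopeFootprint] = {}
    for (ref, partner), prob in table.residue_probability.items():
        if not _is_protomer(ref[0]):
            continue
        keep = prob >= cutoff if inclusive else prob > cutoff
        if not keep:
            continue
        fp = footprints.setdefault(
            partner,
            EpitopeFootprint(antibody=partner, residues={}, cutoff=cutoff,
                             inclusive=inclusive),
        )
        fp.residues[ref] = prob
        if ref in table.names:
            fp.names[ref] = table.names[ref]
    return footprints


def _rotate(protomer: str, k: int, n: int = 6) -> str:
    return f"P{(int(protomer[1:]) - 1 + k) % n + 1}"


def stoichiometry_summary(
    footprints: list[EpitopeFootprint],
    topology: Topology | None = None,
) -> StoichiometrySummary:
    """Count protomers per antibody and test diametric symmetry.

    ``symmetric`` is true iff exactly two non-empty footprints exist and each
    protomer set is the image of the other under rotation by half the ring
    (3 positions for a hexamer).
    """
    if not footprints:
        raise HexitopeError("at least one footprint required")
    known = set(topology.protomers) if topology is not None else None
    n_ring = len(known) if known else 6
    occupied = [fp for fp in footprints if fp.residues]
    per_ab: dict[str, int] = {}
    sets: list[set[str]] = []
    for fp in occupied:
        protomers = fp.protomers
        if known is not None:
            unknown = protomers - known
            if unknown:
                raise LookupFailure(
                    f"footprint {fp.antibody} references unknown protomers {sorted(unknown)}"
                )
        per_ab[fp.antibody] = len(protomers)
        sets.append(protomers)
    symmetric = False
    if len(sets) == 2:
        half = n_ring // 2
        symmetric = {_rotate(p, half, n_ring) for p in sets[0]} == sets[1]
    shared: set[str] = set()
    for i, s in enumerate(sets):
        for t in sets[i + 1:]:
            shared |= s & t
    return StoichiometrySummary(
        n_antibodies=len(occupied),
        protomers_per_antibody=per_ab,
        shared_protomers=shared,
        symmetric=symmetric,
    )
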