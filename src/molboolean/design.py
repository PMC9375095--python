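"""The published oligonucleotide design set and its verification report.

The packaged FASTA file reproduces the assay's DNA design verbatim: the two
circle parts, the probe arms A/B, the reporter tags A/B, the fluorophore
detection oligos (DNA body plus a 3-base U tail, recorded separately), and the
two 99-nt padlock control probes. ``invariant_report`` recomputes every
sequence-level design property from the sequences alone — arm/circle
footprints, nick sites, padlock terminal-footprint arithmetic, tag/arm
complementarity and the nick/tag specificity truth table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .oligo import (
    Circle,
    End5Mod,
    Oligo,
    OligoRole,
    assemble_circle,
    circularize_padlock,
    find_complement_match,
    find_nick_sites,
    hybridization_footprint,
    incorporate_tags,
    nick_circle,
    reverse_complement,
)

__all__ = [
    "load_design_oligos",
    "read_oligos_fasta",
    "write_oligos_fasta",
    "assembled_circle",
    "specificity_truth_table",
    "padlock_arithmetic",
    "invariant_report",
]

_PACKAGED_FASTA = "design_oligos.fasta"


def _record_to_oligo(rec: SeqRecord) -> Oligo:
    attrs = dict(
        token.split("=", 1) for token in rec.description.split()[1:] if "=" in token
    )
    raw = str(rec.seq).upper()
    body = raw.rstrip("U")
    tail = raw[len(body) :]
    return Oligo(
        name=rec.id,
        sequence=body,
        end5_mod=End5Mod(attrs.get("end5", "none")),
        role=OligoRole(attrs.get("role", "detection")),
        tail3=tail,
        label=attrs.get("label", ""),
    )


def read_oligos_fasta(path: "Path | str") -> dict[str, Oligo]:
    """Read an oligo set from FASTA (attributes in ``key=value`` description)."""
    return {rec.id: _record_to_oligo(rec) for rec in SeqIO.parse(str(path), "fasta")}


def write_oligos_fasta(oligos: Iterable[Oligo], path: "Path | str") -> None:
    records = []
    for o in oligos:
        desc = f"end5={o.end5_mod.value} role={o.role.value}"
        if o.label:
            desc += f" label={o.label}"
        records.append(SeqRecord(Seq(o.sequence + o.tail3), id=o.name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def load_design_oligos() -> dict[str, Oligo]:
    """The packaged design set, keyed by oligo name."""
    ref = resources.files("molboolean").joinpath("data", _PACKAGED_FASTA)
    with resources.as_file(ref) as path:
        return read_oligos_fasta(path)


def assembled_circle(oligos: Mapping[str, Oligo] | None = None) -> Circle:
    """The sealed information-receiver circle ligated from parts 1 and 2."""
    oligos = oligos or load_design_oligos()
    return assemble_circle(oligos["circle_part_1"], oligos["circle_part_2"])


def specificity_truth_table(
    oligos: Mapping[str, Oligo] | None = None,
) -> list[dict]:
    """Exhaustive nick/tag specificity table over arm and tag combinations.

    Reproduces the in-solution gel logic: the circle is nicked only when an
    arm is hybridized (one nick per arm), and a tag seals a nick only when its
    cognate arm generated that nick. Rows cover all four bound-arm subsets
    crossed with all four offered-tag subsets.
    """
    oligos = oligos or load_design_oligos()
    circle = assembled_circle(oligos)
    arms = {"A": oligos["arm_A"], "B": oligos["arm_B"]}
    tags = {"A": oligos["tag_A"], "B": oligos["tag_B"]}
    rows = []
    for arm_keys in [(), ("A",), ("B",), ("A", "B")]:
        bound = [arms[k] for k in arm_keys]
        nicked = nick_circle(circle, bound)
        for tag_keys in [(), ("A",), ("B",), ("A", "B")]:
            offered = [tags[k] for k in tag_keys]
            if nicked.sealed:
                final = nicked
            else:
                final = incorporate_tags(nicked, bound, offered)
            incorporated = {t.removeprefix("tag_") for t in final.tags_incorporated}
            rows.append(
                {
                    "bound_arms": "".join(arm_keys),
                    "offered_tags": "".join(tag_keys),
                    "n_nicks": len(nicked.nicks),
                    "sealed": final.sealed,
                    "tags_incorporated": "".join(sorted(incorporated)),
                    "amplifiable": final.sealed,
                }
            )
    return rows


def padlock_arithmetic(oligos: Mapping[str, Oligo] | None = None) -> list[dict]:
    """Terminal-footprint arithmetic of each padlock probe on its arm.

    Reports, per padlock: total length, the longest 5'- and 3'-anchored exact
    reverse-complement footprints on the cognate arm, the implied linker
    length, footprint adjacency, and whether arm-templated circularization
    succeeds. Note the longest-match footprints can exceed the designed
    25/24 nt by a coincidental complementary base adjacent to the designed
    segment; the designed total duplex is 50 nt for both padlocks.
    """
    oligos = oligos or load_design_oligos()
    rows = []
    for suffix in ("A", "B"):
        padlock = oligos[f"padlock_{suffix}"]
        arm = oligos[f"arm_{suffix}"]
        m5 = find_complement_match(padlock, arm, anchor="terminal5")
        m3 = find_complement_match(padlock, arm, anchor="terminal3")
        circ = circularize_padlock(padlock, arm)
        rows.append(
            {
                "padlock": padlock.name,
                "arm": arm.name,
                "length": len(padlock),
                "terminal5_footprint": m5.length,
                "terminal3_footprint": m3.length,
                "linker": len(padlock) - m5.length - m3.length,
                "footprints_adjacent": bool(m5 and m3 and m3.target_start == m5.target_end),
                "circularizes": circ is not None,
                "circle_length": len(circ) if circ is not None else 0,
            }
        )
    return rows


def invariant_report(oligos: Mapping[str, Oligo] | None = None) -> dict:
    """Full sequence-level verification report of a design set.

    Covers circle assembly, arm footprints and nick sites, tag/arm
    complementarity, detection-oligo identity, padlock arithmetic and the
    specificity truth table. All values are recomputed from the sequences.
    """
    oligos = oligos or load_design_oligos()
    circle = assembled_circle(oligos)
    arms = {k: oligos[f"arm_{k}"] for k in ("A", "B")}
    tags = {k: oligos[f"tag_{k}"] for k in ("A", "B")}
    dets = {k: oligos[f"detection_{k}"] for k in ("A", "B")}
    footprints = {
        k: hybridization_footprint(arm, circle) for k, arm in arms.items()
    }
    nicks = {
        k: sorted(find_nick_sites(circle, [arm])) for k, arm in arms.items()
    }
    report = {
        "circle_length": len(circle),
        "circle_sealed": circle.sealed,
        "arm_footprints": {k: [list(iv) for iv in v] for k, v in footprints.items()},
        "nick_sites": nicks,
        "tag_in_arm_loop": {
            k: reverse_complement(tags[k].sequence) in arms[k].sequence
            for k in ("A", "B")
        },
        "detection_matches_tag": {
            k: dets[k].sequence == tags[k].sequence for k in ("A", "B")
        },
        "padlocks": padlock_arithmetic(oligos),
        "truth_table": specificity_truth_table(oligos),
    }
    return report
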