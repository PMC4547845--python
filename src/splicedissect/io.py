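"""On-disk formats: GFF3 event catalogs, VCF 4.2 variants, FASTA, TSV tables.

Internal coordinates are 0-based half-open; GFF3 and VCF output is 1-based
(closed intervals for GFF3), converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .events import EventCatalog, EventModel

__all__ = [
    "write_gff3", "read_gff3", "write_vcf", "read_vcf",
    "write_fasta", "read_fasta", "write_table", "read_table",
]

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]

_SOURCE = "splicedissect"


def _attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v is not None)


def write_gff3(catalog: EventCatalog, path) -> None:
    """Write an event catalog as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in catalog:
            s, e = ev.span
            fh.write("\t".join(map(str, [
                ev.chromosome, _SOURCE, "as_event", s + 1, e, ".",
                ev.strand, ".",
                _attrs(
                    ID=ev.event_id, as_type=ev.as_type,
                    c_inclusion=ev.c_inclusion, c_exclusion=ev.c_exclusion,
                    region_class=ev.region_class, frame_class=ev.frame_class,
                ),
            ])) + "\n")
            for role, segs in (("inclusion", ev.inclusion_segments),
                               ("exclusion", ev.exclusion_segments)):
                for i, (ss, se) in enumerate(segs, 1):
                    fh.write("\t".join(map(str, [
                        ev.chromosome, _SOURCE, "isoform_segment",
                        ss + 1, se, ".", ev.strand, ".",
                        _attrs(ID=f"{ev.event_id}.{role}.{i}",
                               Parent=ev.event_id, role=role),
                    ])) + "\n")
            for i, (cs, ce) in enumerate(ev.cds, 1):
                fh.write("\t".join(map(str, [
                    ev.chromosome, _SOURCE, "CDS", cs + 1, ce, ".",
                    ev.strand, ".",
                    _attrs(ID=f"{ev.event_id}.cds.{i}", Parent=ev.event_id),
                ])) + "\n")


def read_gff3(path) -> EventCatalog:
    """Read an event catalog written by :func:`write_gff3`."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, dtype={"seqid": str}
    )
    attr_dicts = df["attributes"].map(
        lambda a: dict(kv.split("=", 1) for kv in a.split(";"))
    )
    df = df.assign(
        ID=[a.get("ID") for a in attr_dicts],
        Parent=[a.get("Parent") for a in attr_dicts],
        role=[a.get("role") for a in attr_dicts],
        _attr=attr_dicts,
    )
    events = []
    for _, row in df[df["type"] == "as_event"].iterrows():
        eid = row["ID"]
        children = df[df["Parent"] == eid]
        inc = [
            (int(r["start"]) - 1, int(r["end"]))
            for _, r in children[children["role"] == "inclusion"].iterrows()
        ]
        exc = [
            (int(r["start"]) - 1, int(r["end"]))
            for _, r in children[children["role"] == "exclusion"].iterrows()
        ]
        cds = [
            (int(r["start"]) - 1, int(r["end"]))
            for _, r in children[children["type"] == "CDS"].iterrows()
        ]
        a = row["_attr"]
        events.append(EventModel(
            event_id=eid,
            as_type=a["as_type"],
            chromosome=row["seqid"],
            strand=row["strand"],
            inclusion_segments=tuple(sorted(inc)),
            exclusion_segments=tuple(sorted(exc)),
            c_inclusion=float(a.get("c_inclusion", 1.0)),
            c_exclusion=float(a.get("c_exclusion", 1.0)),
            region_class=a.get("region_class", "coding"),
            frame_class=a.get("frame_class", "not-applicable"),
            cds=tuple(sorted(cds)),
        ))
    return EventCatalog(events)


def write_vcf(variants: pd.DataFrame, path, contigs: dict[str, int] | None = None):
    """Write a variant table (chromosome, position 0-based, ref, alt) as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={_SOURCE}\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(variants.itertuples(index=False), 1):
            fh.write(
                f"{v.chromosome}\t{int(v.position) + 1}\tvar{i:07d}\t"
                f"{v.ref}\t{v.alt}\t.\tPASS\t.\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into the internal variant table (0-based positions)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _vid, ref, alt = line.rstrip("\n").split("\t")[:5]
            if len(ref) == len(alt) == 1:
                vclass = "SNV"
            elif len(alt) > len(ref):
                vclass = "insertion"
            else:
                vclass = "deletion"
            rows.append((chrom, int(pos) - 1, ref, alt, vclass))
    return pd.DataFrame(
        rows, columns=["chromosome", "position", "ref", "alt", "vclass"]
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
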