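"""File formats at the package boundary.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based,
inclusive) and BED (0-based, half-open) conversions happen only here.
Hits travel as 12-column BLAST tabular (outfmt 6) extended with a 13th
strand column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel, Hsp
from .clusters import GeneCluster
from .simulate import RefProtein, SimTruth, TruthGene

HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "strand",
]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:  # pragma: no cover - biopython raises variously
        raise ValueError(f"malformed FASTA file {path}: {exc}") from exc


def write_references(refs: list[RefProtein], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_family: dict[str, dict[str, str]] = {}
    for ref in refs:
        name = ref.id if ref.subtype is None else f"{ref.id}|subtype={ref.subtype}"
        by_family.setdefault(ref.family, {})[name] = ref.seq
    for family, seqs in by_family.items():
        write_fasta(seqs, directory / f"{family}.fa")


def read_references(directory) -> list[RefProtein]:
    refs = []
    for path in sorted(Path(directory).glob("*.fa")):
        family = path.stem
        for name, seq in read_fasta(path).items():
            subtype = None
            if "|subtype=" in name:
                name, subtype = name.split("|subtype=", 1)
            refs.append(RefProtein(name, family, subtype, seq))
    if not refs:
        raise ValueError(f"no reference FASTA files found in {directory}")
    return refs


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive at this boundary)


def _gff_line(scaffold, source, ftype, start, end, strand, attrs) -> str:
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{scaffold}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr}"


def write_models_gff(models: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = {"ID": m.id, "family": m.family, "status": m.status}
        if m.subtype:
            attrs["subtype"] = m.subtype
        lines.append(_gff_line(m.scaffold, "olfrep", "gene", m.start, m.end,
                               m.strand, attrs))
        for k, (s, e) in enumerate(m.exons):
            lines.append(
                _gff_line(m.scaffold, "olfrep", "CDS", s, e, m.strand,
                          {"ID": f"{m.id}.cds{k + 1}", "Parent": m.id})
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_gff(truth: SimTruth, path) -> None:
    lines = ["##gff-version 3"]
    for g in truth.genes:
        attrs = {
            "ID": g.id,
            "family": g.family,
            "intact": str(g.intact).lower(),
        }
        if g.subtype:
            attrs["subtype"] = g.subtype
        if g.cluster_id:
            attrs["cluster"] = g.cluster_id
        lines.append(_gff_line(g.scaffold, "olfrep_sim", "gene", g.start, g.end,
                               g.strand, attrs))
        for k, (s, e) in enumerate(g.exons):
            lines.append(
                _gff_line(g.scaffold, "olfrep_sim", "CDS", s, e, g.strand,
                          {"ID": f"{g.id}.cds{k + 1}", "Parent": g.id})
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_models_gff(path, proteins: dict[str, str] | None = None) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 {path} line {lineno}")
        scaffold, _src, ftype, start, end, _score, strand, _phase, attr = fields
        attrs = _parse_attrs(attr)
        start0, end0 = int(start) - 1, int(end)
        if ftype == "gene":
            genes[attrs["ID"]] = {
                "id": attrs["ID"],
                "family": attrs.get("family", "OR"),
                "subtype": attrs.get("subtype"),
                "scaffold": scaffold,
                "start": start0,
                "end": end0,
                "strand": strand,
                "status": attrs.get("status", "intact"),
                "exons": [],
            }
        elif ftype == "CDS":
            genes[attrs["Parent"]]["exons"].append((start0, end0))
    models = []
    for g in genes.values():
        exons = tuple(sorted(g["exons"])) or ((g["start"], g["end"]),)
        models.append(
            GeneModel(
                id=g["id"],
                family=g["family"],
                subtype=g["subtype"],
                scaffold=g["scaffold"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                exons=exons,
                protein=(proteins or {}).get(g["id"], ""),
                status=g["status"],
            )
        )
    models.sort(key=lambda m: (m.scaffold, m.start, m.end))
    return models


# ---------------------------------------------------------------------------
# hits (BLAST outfmt-6 dialect + strand)


def write_hits(hsps: list[Hsp], path) -> None:
    rows = []
    for h in hsps:
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.scaffold,
                "pident": 0.0,
                "length": h.query_end - h.query_start,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": h.query_start + 1,
                "qend": h.query_end,
                "sstart": h.target_start + 1,
                "send": h.target_end,
                "evalue": 0.0,
                "bitscore": h.score,
                "strand": h.strand,
            }
        )
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits(path, family_of: dict[str, str]) -> list[Hsp]:
    """Read tabular hits; ``family_of`` maps query ids to receptor families."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in HITS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"hit table {path} lacks columns {missing}")
    hsps = []
    for _, row in table.iterrows():
        hsps.append(
            Hsp(
                query_id=str(row["qseqid"]),
                query_family=family_of.get(str(row["qseqid"]), "OR"),
                scaffold=str(row["sseqid"]),
                target_start=int(row["sstart"]) - 1,
                target_end=int(row["send"]),
                strand=str(row["strand"]),
                query_start=int(row["qstart"]) - 1,
                query_end=int(row["qend"]),
                score=float(row["bitscore"]),
                frame=0,
            )
        )
    return hsps


# ---------------------------------------------------------------------------
# clusters


def write_clusters(clusters: list[GeneCluster], bed_path, json_path) -> None:
    with open(bed_path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.scaffold}\t{c.start}\t{c.end}\t{c.id}\t{c.size}\t.\n")
    payload = [
        {
            "id": c.id,
            "scaffold": c.scaffold,
            "start": c.start,
            "end": c.end,
            "members": list(c.members),
            "family_counts": c.family_counts,
        }
        for c in clusters
    ]
    Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_clusters(json_path) -> list[GeneCluster]:
    payload = json.loads(Path(json_path).read_text())
    return [
        GeneCluster(
            id=c["id"],
            scaffold=c["scaffold"],
            members=tuple(c["members"]),
            start=c["start"],
            end=c["end"],
            family_counts=c.get("family_counts", {}),
        )
    for c in payload]
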