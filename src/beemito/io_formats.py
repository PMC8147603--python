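"""Readers and writers for the file formats the pipeline touches.

Sequences travel as FASTA, sample metadata and microsatellite genotypes as
delimited tables, and haplotype networks as edge-list/node TSV pairs with an
optional GraphML mirror.  Parsers are strict: duplicate ids, unmatched
metadata and malformed genotype cells raise instead of warning, so record
counts are conserved end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MtSequence",
    "GenotypeTable",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "attach_metadata",
    "read_genotypes",
    "write_genotypes",
    "write_network",
    "read_network",
    "haversine_km",
]

#: sentinel values treated as a missing genotype cell
_MISSING_TOKENS = {"", "na", "nan", "none", "-", ".", "?"}

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MtSequence:
    """One sampled bee: its COI-COII sequence plus geographic metadata."""

    sample_id: str
    seq: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    country: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence for {self.sample_id!r} is empty")
        if self.latitude is not None and abs(self.latitude) > 90:
            raise ValueError(f"{self.sample_id}: |latitude| > 90")
        if self.longitude is not None and abs(self.longitude) > 180:
            raise ValueError(f"{self.sample_id}: |longitude| > 180")

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class GenotypeTable:
    """Diploid microsatellite genotypes: unordered allele pairs per locus.

    ``alleles[sample_id][locus]`` is a sorted ``(a, b)`` tuple of integer
    allele labels, or ``None`` for a missing genotype.
    """

    sample_ids: list[str]
    loci: list[str]
    alleles: dict = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("at least one locus required")

    def genotype(self, sample_id: str, locus: str):
        return self.alleles[sample_id][locus]


def read_fasta(path, metadata: Optional[pd.DataFrame] = None) -> list[MtSequence]:
    """Read FASTA into :class:`MtSequence` records, in file order.

    Sequences are uppercased and RNA 'U' mapped to 'T'.  Duplicate record
    ids and empty files are errors.  If ``metadata`` is given, coordinates
    are joined by exact sample id (see :func:`attach_metadata`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[MtSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(MtSequence(rec.id, str(rec.seq).upper().replace("U", "T")))
    if metadata is not None:
        attach_metadata(out, metadata)
    return out


def write_fasta(seqs: list[MtSequence], path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.sample_id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path) -> pd.DataFrame:
    """Read a delimited sample table (sample_id, latitude, longitude[, country])."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"sample_id": str})
    required = {"sample_id", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in metadata")
    return df


def attach_metadata(seqs: list[MtSequence], metadata: pd.DataFrame) -> list[MtSequence]:
    """Join coordinates onto sequences by exact id; unmatched ids are an error."""
    meta = metadata.set_index("sample_id")
    for s in seqs:
        if s.sample_id not in meta.index:
            raise KeyError(f"sample {s.sample_id!r} absent from metadata")
        row = meta.loc[s.sample_id]
        s.latitude = float(row["latitude"])
        s.longitude = float(row["longitude"])
        if "country" in meta.columns and not pd.isna(row.get("country")):
            s.country = str(row["country"])
        if abs(s.latitude) > 90 or abs(s.longitude) > 180:
            raise ValueError(f"{s.sample_id}: coordinates out of range")
    return seqs


def _parse_pair_cell(cell, sample_id: str, locus: str):
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    if "/" not in text:
        raise ValueError(
            f"genotype cell {text!r} for sample {sample_id!r}, locus {locus!r} "
            "does not hold exactly 2 alleles (expected 'a/b')"
        )
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(
            f"genotype cell {text!r} for sample {sample_id!r}, locus {locus!r} "
            "has an odd allele count"
        )
    a, b = (int(p) for p in parts)
    return tuple(sorted((a, b)))


def read_genotypes(path) -> GenotypeTable:
    """Read a diploid genotype table.

    Two dialects are auto-detected:

    * one column per locus with ``a/b`` cells;
    * two adjacent columns per locus (``L1`` and ``L1.1`` or ``L1_2`` style
      suffixes), one allele each.

    The first column is the sample id.  Allele pairs are stored unordered;
    blank/NA cells become missing genotypes.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    id_col = df.columns[0]
    value_cols = list(df.columns[1:])
    if not value_cols:
        raise ValueError("genotype table has no locus columns")
    sample_ids = df[id_col].astype(str).tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in genotype table")

    body = df[value_cols]
    slash = body.apply(lambda c: c.astype(str).str.contains("/", na=False)).to_numpy()
    if slash.any():
        loci = value_cols
        alleles = {
            sid: {
                loc: _parse_pair_cell(df.at[i, loc], sid, loc) for loc in loci
            }
            for i, sid in zip(df.index, sample_ids)
        }
    else:
        if len(value_cols) % 2 != 0:
            raise ValueError(
                f"two-column genotype dialect needs an even number of allele "
                f"columns, got {len(value_cols)} (odd allele count for a locus)"
            )
        loci = []
        alleles = {sid: {} for sid in sample_ids}
        for k in range(0, len(value_cols), 2):
            c1, c2 = value_cols[k], value_cols[k + 1]
            locus = c1.rstrip("0123456789").rstrip("._-") or c1
            if locus in loci:
                locus = c1
            loci.append(locus)
            for i, sid in zip(df.index, sample_ids):
                v1, v2 = df.at[i, c1], df.at[i, c2]
                miss1 = pd.isna(v1) or str(v1).strip().lower() in _MISSING_TOKENS
                miss2 = pd.isna(v2) or str(v2).strip().lower() in _MISSING_TOKENS
                if miss1 != miss2:
                    raise ValueError(
                        f"sample {sid!r}, locus {locus!r}: odd allele count "
                        "(one of two allele columns missing)"
                    )
                alleles[sid][locus] = (
                    None if miss1 else tuple(sorted((int(v1), int(v2))))
                )
    return GenotypeTable(sample_ids, list(loci), alleles)


def write_genotypes(gt: GenotypeTable, path) -> None:
    """Write a genotype table in the ``a/b`` one-column-per-locus dialect."""
    rows = []
    for sid in gt.sample_ids:
        row = {"sample_id": sid}
        for loc in gt.loci:
            g = gt.alleles[sid][loc]
            row[loc] = "" if g is None else f"{g[0]}/{g[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_NETWORK_FORMATS = ("tsv", "graphml")


def write_network(network: nx.Graph, out_prefix, format: str = "tsv") -> list[Path]:
    """Write a haplotype network.

    ``tsv`` writes ``<prefix>.edges.tsv`` (node1, node2, steps) and
    ``<prefix>.nodes.tsv`` (node, count, inferred); ``graphml`` writes
    ``<prefix>.graphml``.  Median (inferred) nodes carry count 0 and
    ``inferred=1``.
    """
    if format not in _NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; supported: {list(_NETWORK_FORMATS)}"
        )
    out_prefix = Path(out_prefix)
    written: list[Path] = []
    if format == "tsv":
        edges = pd.DataFrame(
            [(u, v, 1) for u, v in sorted(map(lambda e: tuple(sorted(e)), network.edges()))],
            columns=["node1", "node2", "steps"],
        )
        nodes = pd.DataFrame(
            [
                (
                    n,
                    int(network.nodes[n].get("count", 0)),
                    int(bool(network.nodes[n].get("inferred", False))),
                )
                for n in sorted(network.nodes())
            ],
            columns=["node", "count", "inferred"],
        )
        ep = Path(str(out_prefix) + ".edges.tsv")
        np_ = Path(str(out_prefix) + ".nodes.tsv")
        edges.to_csv(ep, sep="\t", index=False)
        nodes.to_csv(np_, sep="\t", index=False)
        written += [ep, np_]
    else:
        g = nx.Graph()
        for n, d in network.nodes(data=True):
            g.add_node(n, count=int(d.get("count", 0)), inferred=bool(d.get("inferred", False)))
        g.add_edges_from(network.edges())
        gp = Path(str(out_prefix) + ".graphml")
        nx.write_graphml(g, gp)
        written.append(gp)
    return written


def read_network(out_prefix) -> nx.Graph:
    """Read back a network written by :func:`write_network` in tsv format."""
    out_prefix = Path(out_prefix)
    nodes = pd.read_csv(str(out_prefix) + ".nodes.tsv", sep="\t")
    edges = pd.read_csv(str(out_prefix) + ".edges.tsv", sep="\t")
    g = nx.Graph()
    for _, r in nodes.iterrows():
        g.add_node(str(r["node"]), count=int(r["count"]), inferred=bool(r["inferred"]))
    for _, r in edges.iterrows():
        g.add_edge(str(r["node1"]), str(r["node2"]))
    return g


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points (haversine)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
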