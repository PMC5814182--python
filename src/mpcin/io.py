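"""Readers and writers for the formats the pipeline touches.

Coordinates are 0-based half-open throughout, matching BED/BEDPE.
Fragments travel as 10-column BEDPE (each end as a 1-base interval with its
strand), segments as BED4+score (name = gain/normal/loss, score = cn x 100
rounded), genomes as FASTA plus a JSON description (lengths, transgenes,
expected copies, per-bin GC), truth sets as JSON, expression matrices and
manifests as TSV. Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CNVSegment, CopyNumberTrack
from .fragments import FRAGMENT_COLUMNS, canonicalize
from .junctions import BreakpointJunction, IntegrationSite, junctions_to_frame
from .simulate.genome import GenomeModel
from .simulate.karyotype import TruthSet

_BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score", "strand1", "strand2",
]


# ----------------------------------------------------------------------
# fragments (BEDPE)
# ----------------------------------------------------------------------

def write_fragments(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a fragment frame as 10-column BEDPE."""
    out = pd.DataFrame(
        {
            "chrom1": frame["chrom1"],
            "start1": frame["pos1"],
            "end1": frame["pos1"] + 1,
            "chrom2": frame["chrom2"],
            "start2": frame["pos2"],
            "end2": frame["pos2"] + 1,
            "name": frame["name"],
            "score": 0,
            "strand1": frame["strand1"],
            "strand2": frame["strand2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read 10-column BEDPE into a validated fragment frame.

    Malformed rows are reported with 1-based line numbers; with a genome,
    chromosomes and positions are validated and ends canonicalized.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(10))
    if raw.shape[1] < 10:
        raise ValueError(
            f"{path}: BEDPE needs 10 columns (incl. strand1/strand2), found {raw.shape[1]}"
        )
    raw = raw.iloc[:, :10]
    raw.columns = _BEDPE_COLUMNS
    for col in ("start1", "start2"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"{path}: malformed coordinate in column {col} at line {line}")
        raw[col] = converted.astype(np.int64)
    frame = pd.DataFrame(
        {
            "chrom1": raw["chrom1"],
            "pos1": raw["start1"],
            "strand1": raw["strand1"],
            "chrom2": raw["chrom2"],
            "pos2": raw["start2"],
            "strand2": raw["strand2"],
            "name": raw["name"],
        },
        columns=FRAGMENT_COLUMNS,
    )
    bad = ~frame["strand1"].isin(("+", "-")) | ~frame["strand2"].isin(("+", "-"))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: invalid strand at line {line}")
    if genome is not None:
        frame = canonicalize(frame, genome)
    return frame


# ----------------------------------------------------------------------
# segments (BED)
# ----------------------------------------------------------------------

def write_segments_bed(segments: list[CNVSegment], path: str | Path) -> None:
    """BED4+score; segments must partition each chromosome (no overlap)."""
    by_chrom: dict[str, list[CNVSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for left, right in zip(segs, segs[1:]):
            if right.start < left.end:
                raise ValueError(
                    f"segments overlap on {chrom!r}: [{left.start},{left.end}) and "
                    f"[{right.start},{right.end})"
                )
    lines = ["#chrom\tstart\tend\tname\tscore"]
    for s in segments:
        name = s.klass if s.klass is not None else "unclassified"
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{round(s.cn_mean * 100)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# genome (FASTA + JSON description)
# ----------------------------------------------------------------------

def write_genome_fasta(genome: GenomeModel, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if genome.sequence is None:
        raise ValueError("genome has no sequence; write the JSON description instead")
    records = [
        SeqRecord(Seq(genome.sequence[name]), id=name, description="")
        for name, _ in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_chrom_lengths(genome: GenomeModel, path: str | Path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False
    )


def write_genome_json(genome: GenomeModel, path: str | Path) -> None:
    """Sequence-free genome description: lengths, GC track, transgenes."""
    data = {
        "bin_size": genome.bin_size,
        "chromosomes": [[n, int(l)] for n, l in genome.chromosomes],
        "transgenes": list(genome.transgenes),
        "expected_copies": genome.expected_copies,
        "gc": {name: [round(float(v), 6) for v in genome.gc[name]] for name, _ in genome.chromosomes},
    }
    Path(path).write_text(json.dumps(data, sort_keys=True))


def read_genome_json(path: str | Path) -> GenomeModel:
    data = json.loads(Path(path).read_text())
    return GenomeModel(
        chromosomes=[(n, int(l)) for n, l in data["chromosomes"]],
        bin_size=int(data["bin_size"]),
        transgenes=tuple(data["transgenes"]),
        gc={name: np.asarray(track, dtype=float) for name, track in data["gc"].items()},
        expected_copies={k: int(v) for k, v in data["expected_copies"].items()},
    )


# ----------------------------------------------------------------------
# truth sets (JSON)
# ----------------------------------------------------------------------

def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    data = {
        "cn_segments": [[c, int(s), int(e), int(k)] for c, s, e, k in truth.cn_segments],
        "junctions": [
            {"locusA": list(a), "locusB": list(b), "class": klass}
            for a, b, klass in truth.junctions
        ],
        "integration_sites": [[t, c, int(p)] for t, c, p in truth.integration_sites],
        "chromoplexy_components": [list(c) for c in truth.chromoplexy_components],
        "expression_effects": truth.expression_effects,
    }
    Path(path).write_text(json.dumps(data, sort_keys=True))


def read_truth_json(path: str | Path) -> TruthSet:
    data = json.loads(Path(path).read_text())
    return TruthSet(
        cn_segments=[(c, int(s), int(e), int(k)) for c, s, e, k in data["cn_segments"]],
        junctions=[
            ((j["locusA"][0], int(j["locusA"][1]), j["locusA"][2]),
             (j["locusB"][0], int(j["locusB"][1]), j["locusB"][2]),
             j["class"])
            for j in data["junctions"]
        ],
        integration_sites=[(t, c, int(p)) for t, c, p in data["integration_sites"]],
        chromoplexy_components=[tuple(c) for c in data["chromoplexy_components"]],
        expression_effects={k: float(v) for k, v in data["expression_effects"].items()},
    )


# ----------------------------------------------------------------------
# expression / manifest (TSV)
# ----------------------------------------------------------------------

def write_expression_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene")
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene names: {dupes}")
    return counts


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------

def write_track_tsv(track: CopyNumberTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def write_junctions_tsv(junctions: list[BreakpointJunction], path: str | Path) -> None:
    junctions_to_frame(junctions).to_csv(path, sep="\t", index=False)


def write_sites(sites: list[IntegrationSite], bed_path: str | Path, tsv_path: str | Path) -> None:
    lines = [f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.transgene}" for s in sites]
    Path(bed_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    pd.DataFrame(
        [{"transgene": s.transgene, "chrom": s.chrom, "pos": s.pos, "support": s.support} for s in sites],
        columns=["transgene", "chrom", "pos", "support"],
    ).to_csv(tsv_path, sep="\t", index=False)
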