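"""Alignment and annotation I/O for 3'-end analysis.

Conventions used throughout the package:

* internal coordinates are 0-based half-open;
* GTF/GFF3 input is 1-based inclusive and converted on load;
* BED output is 0-based half-open;
* a read's 3' end is the last aligned base: ``end - 1`` on the + strand
  and ``start`` on the - strand (soft-clipped bases are excluded because
  the *alignment* end, not the query end, is used).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from gffutils.feature import feature_from_line

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


@dataclass(frozen=True)
class AlignedRead:
    """A single alignment with the attributes the 3'-end filters need.

    ``junctions`` are intron intervals (0-based half-open), sorted,
    non-overlapping and strictly inside ``[start, end)``.  ``max_indel``
    is the largest single insertion or deletion in the alignment.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    is_primary: bool = True
    max_indel: int = 0
    junctions: tuple = ()
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValidationError(f"read {self.read_id}: strand {self.strand!r} not in {STRANDS}")
        if not self.start < self.end:
            raise ValidationError(f"read {self.read_id}: start {self.start} >= end {self.end}")
        prev = self.start
        for js, je in self.junctions:
            if not (self.start < js < je < self.end):
                raise ValidationError(f"read {self.read_id}: junction ({js},{je}) outside read body")
            if js < prev:
                raise ValidationError(f"read {self.read_id}: junctions unsorted or overlapping")
            prev = je


@dataclass(frozen=True)
class LocusAnnotation:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    source_gene_ids: tuple = ()

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValidationError(f"locus {self.locus_id}: strand {self.strand!r} invalid")
        if not self.start < self.end:
            raise ValidationError(f"locus {self.locus_id}: start >= end")


@dataclass
class ThreePrimeProfile:
    """Multiset of read 3'-end genomic coordinates for one locus/condition."""

    locus_id: str
    condition: str
    positions: np.ndarray
    strand: str

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValidationError(f"profile {self.locus_id}: strand {self.strand!r} invalid")
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def n_reads(self) -> int:
        return int(self.positions.size)


def _locus_key(feature) -> str | None:
    for key in ("gene_id", "locus_id", "ID", "Parent", "transcript_id"):
        if key in feature.attributes:
            val = feature.attributes[key]
            return val[0] if isinstance(val, list) else val
    return None


def load_loci(annotation) -> list[LocusAnnotation]:
    """Parse a GTF/GFF3 stream into merged transcriptional loci.

    Records sharing a gene/locus key are merged into a single locus
    spanning their union.  File coordinates (1-based inclusive) are
    converted to 0-based half-open.

    Parameters
    ----------
    annotation : path, file object or iterable of lines.
    """
    if isinstance(annotation, (str, Path)):
        lines = Path(annotation).read_text().splitlines()
    elif hasattr(annotation, "read"):
        lines = annotation.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in annotation]

    merged: dict[str, dict] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise ValidationError(f"malformed annotation record at line {lineno}: {exc}") from exc
        key = _locus_key(feat)
        if key is None:
            raise ValidationError(f"annotation record at line {lineno} has no gene/locus identifier")
        if feat.strand not in STRANDS:
            raise ValidationError(f"annotation record at line {lineno}: strand {feat.strand!r}")
        start0, end0 = feat.start - 1, feat.end
        entry = merged.get(key)
        if entry is None:
            merged[key] = {
                "chrom": feat.seqid, "start": start0, "end": end0,
                "strand": feat.strand, "genes": set(),
            }
            entry = merged[key]
        else:
            if entry["strand"] != feat.strand:
                raise ValidationError(f"locus {key!r}: conflicting strands across records")
            if entry["chrom"] != feat.seqid:
                raise ValidationError(f"locus {key!r}: records on multiple chromosomes")
            entry["start"] = min(entry["start"], start0)
            entry["end"] = max(entry["end"], end0)
        gid = feat.attributes.get("gene_id")
        if gid:
            entry["genes"].add(gid[0] if isinstance(gid, list) else gid)
    return [
        LocusAnnotation(k, v["chrom"], v["start"], v["end"], v["strand"],
                        tuple(sorted(v["genes"])))
        for k, v in merged.items()
    ]


def _max_indel_and_junctions(aln: pysam.AlignedSegment) -> tuple[int, tuple]:
    max_indel = 0
    junctions = []
    pos = aln.reference_start
    for op, length in aln.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            pos += length
        elif op == 1:  # I
            max_indel = max(max_indel, length)
        elif op == 2:  # D
            max_indel = max(max_indel, length)
            pos += length
        elif op == 3:  # N: intron
            junctions.append((pos, pos + length))
            pos += length
    return max_indel, tuple(junctions)


def read_alignments(path, sample_id: str = "", replicate_id: str = "",
                    require_mapped: bool = True) -> list[AlignedRead]:
    """Load a SAM/BAM file into :class:`AlignedRead` records."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                if require_mapped:
                    continue
                raise ValidationError(f"unmapped read {aln.query_name}")
            max_indel, junctions = _max_indel_and_junctions(aln)
            reads.append(AlignedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                is_primary=not (aln.is_secondary or aln.is_supplementary),
                max_indel=max_indel,
                junctions=junctions,
                sample_id=sample_id,
                replicate_id=replicate_id,
            ))
    return reads


def filter_alignments(reads: Sequence[AlignedRead], max_indel: float = np.inf,
                      min_mapq: int = 0, primary_only: bool = False) -> list[AlignedRead]:
    """Apply alignment-level filters; order is preserved.

    ``max_indel`` is inclusive: a read is removed only when its largest
    indel *exceeds* the threshold (the Helicos-style ">4 nt" rule keeps
    4-nt indels and removes 5-nt ones).
    """
    return [
        r for r in reads
        if r.max_indel <= max_indel
        and r.mapq >= min_mapq
        and (r.is_primary or not primary_only)
    ]


def three_prime_end(read: AlignedRead) -> int:
    return read.end - 1 if read.strand == "+" else read.start


def extract_three_prime_ends(
    reads: Sequence[AlignedRead],
    loci: Sequence[LocusAnnotation],
    flank: int = 0,
) -> tuple[dict, dict]:
    """Build strand-aware per-locus 3'-end profiles.

    Each read is assigned to the same-strand locus it overlaps most
    (ties: lexicographically smallest locus_id).  Reads overlapping no
    locus, or whose 3' end falls outside the assigned locus extended by
    ``flank``, are dropped and counted in the summary.

    Returns
    -------
    profiles : ``{locus_id: {condition: ThreePrimeProfile}}``
    summary : dict with ``n_input``, ``n_assigned``, ``n_unassigned``,
        ``n_end_outside_flank``.
    """
    by_group: dict[tuple, list[LocusAnnotation]] = {}
    for loc in loci:
        by_group.setdefault((loc.chrom, loc.strand), []).append(loc)
    index = {}
    for key, group in by_group.items():
        group = sorted(group, key=lambda l: l.locus_id)
        index[key] = (
            np.array([l.start for l in group]),
            np.array([l.end for l in group]),
            group,
        )

    collected: dict[tuple, list[int]] = {}
    locus_meta = {l.locus_id: l for l in loci}
    n_unassigned = 0
    n_outside = 0
    # deterministic regardless of input order: reads only ever append to
    # per-(locus, condition) multisets, which are order-insensitive
    for read in reads:
        grp = index.get((read.chrom, read.strand))
        if grp is None:
            n_unassigned += 1
            continue
        starts, ends, group = grp
        overlap = np.minimum(ends, read.end) - np.maximum(starts, read.start)
        best = int(np.argmax(overlap))  # argmax takes first max: lexicographic tie-break
        if overlap[best] <= 0:
            n_unassigned += 1
            continue
        locus = group[best]
        end3 = three_prime_end(read)
        if not (locus.start - flank <= end3 < locus.end + flank):
            n_outside += 1
            continue
        collected.setdefault((locus.locus_id, read.sample_id), []).append(end3)

    profiles: dict[str, dict[str, ThreePrimeProfile]] = {}
    for (locus_id, condition), positions in collected.items():
        profiles.setdefault(locus_id, {})[condition] = ThreePrimeProfile(
            locus_id, condition, np.sort(np.array(positions)), locus_meta[locus_id].strand
        )
    summary = {
        "n_input": len(reads),
        "n_assigned": len(reads) - n_unassigned - n_outside,
        "n_unassigned": n_unassigned,
        "n_end_outside_flank": n_outside,
    }
    return profiles, summary


def extract_junction_counts(
    reads: Sequence[AlignedRead],
    junction_catalog: Mapping[str, Iterable[tuple]],
) -> pd.DataFrame:
    """Count exact-coordinate splice-junction support per locus and sample.

    A read increments a catalog junction once per matching intron
    interval (exact start and end).  Catalog junctions with no support
    appear as zero rows.
    """
    samples = sorted({r.sample_id for r in reads})
    counts: dict[tuple, int] = {}
    for locus_id, junctions in junction_catalog.items():
        for js, je in junctions:
            for s in (samples or [pd.NA]):
                counts[(locus_id, int(js), int(je), s)] = 0
    by_junction: dict[tuple, list] = {}
    for key in counts:
        by_junction.setdefault(key[1:3], []).append(key)
    for read in reads:
        for intron in read.junctions:
            for key in by_junction.get((int(intron[0]), int(intron[1])), ()):
                if key[3] is pd.NA or key[3] == read.sample_id:
                    counts[key] += 1
    frame = pd.DataFrame(
        [(l, s_, e_, smp, c) for (l, s_, e_, smp), c in counts.items()],
        columns=["locus_id", "junction_start", "junction_end", "sample_id", "count"],
    )
    return frame.sort_values(["locus_id", "junction_start", "junction_end", "sample_id"],
                             ignore_index=True)


RESULT_COLUMNS = [
    "locus_id", "n_treatment", "n_control", "emd", "mean_shift",
    "p_value", "fdr", "call",
]


def write_results_tsv(frame: pd.DataFrame, path) -> None:
    """Write a results table with deterministic column order."""
    cols = [c for c in RESULT_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(records: Iterable[tuple], path) -> None:
    """Write BED6 lines from (chrom, start, end, name, score, strand).

    The score column carries the locus EMD clipped to [0, 1000].
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            score = int(min(max(score, 0), 1000))
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_run_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
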