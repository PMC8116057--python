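"""Removal of false 3' ends caused by nanopore read oversplitting.

When the signal from one RNA molecule is segmented into several reads,
those fragments pass through the same pore consecutively and map close
together on the genome.  Because native RNA is fed into the pore 3' end
first, only the earliest fragment carries the genuine 3' end; the filter
keeps the most-3' member of each chain and removes the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .read_io import AlignedRead, ValidationError


@dataclass(frozen=True)
class SequencedReadMeta:
    """Per-read pore/channel metadata from a sequencing summary."""

    read_id: str
    channel_id: str
    order_index: int | None = None
    start_time: float | None = None


@dataclass(frozen=True)
class OversplitChain:
    read_ids: tuple
    chrom: str
    strand: str
    kept_read_id: str

    def __post_init__(self):
        if len(self.read_ids) < 2:
            raise ValidationError("oversplit chain must contain at least 2 reads")
        if self.kept_read_id not in self.read_ids:
            raise ValidationError("kept read must be a chain member")


def rank_channel_order(meta: Sequence[SequencedReadMeta]) -> list[SequencedReadMeta]:
    """Assign dense per-channel temporal ranks from start times.

    Ties in start_time are broken by read_id (lexicographic).
    """
    seen = set()
    for m in meta:
        key = (m.channel_id, m.start_time, m.read_id)
        if key in seen:
            raise ValidationError(f"duplicate metadata record {key}")
        seen.add(key)
        if m.start_time is None:
            raise ValidationError(f"read {m.read_id}: start_time required for ranking")
    by_channel: dict[str, list[SequencedReadMeta]] = {}
    for m in meta:
        by_channel.setdefault(m.channel_id, []).append(m)
    ranked = []
    for members in by_channel.values():
        members.sort(key=lambda m: (m.start_time, m.read_id))
        ranked.extend(replace(m, order_index=i) for i, m in enumerate(members))
    ranked.sort(key=lambda m: m.read_id)
    return ranked


def _gap(a: AlignedRead, b: AlignedRead) -> int:
    """Distance between nearest alignment boundaries; 0 if overlapping."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def find_oversplit_chains(
    reads: Sequence[AlignedRead],
    meta: Sequence[SequencedReadMeta],
    max_gap: int = 1000,
    max_time_gap: float | None = None,
    strict: bool = True,
) -> tuple[list[OversplitChain], dict]:
    """Identify maximal chains of consecutively sequenced, contiguously
    mapped reads.

    Two reads are chained iff they share a channel, their temporal ranks
    differ by exactly 1, they map to the same chromosome and strand, and
    the gap between their alignments is at most ``max_gap`` nt (default
    1 kb).  The kept member is the most 3' in transcriptional
    orientation (largest end on +, smallest start on -); ties go to the
    later-sequenced read.

    Reads lacking metadata raise in strict mode; in lenient mode they
    pass the filter untouched and are counted in the report.
    """
    if max_gap <= 0:
        raise ValidationError("max_gap must be positive")
    meta_by_id = {m.read_id: m for m in meta}
    missing = [r.read_id for r in reads if r.read_id not in meta_by_id]
    if missing and strict:
        raise ValidationError(f"{len(missing)} reads without sequencing metadata "
                              f"(first: {missing[0]})")
    channels: dict[str, list[tuple]] = {}
    for r in reads:
        m = meta_by_id.get(r.read_id)
        if m is None:
            continue
        if m.order_index is None:
            raise ValidationError(f"read {r.read_id}: metadata has no order_index; "
                                  "run rank_channel_order first")
        channels.setdefault(m.channel_id, []).append((m.order_index, m, r))

    chains: list[OversplitChain] = []
    for members in channels.values():
        members.sort(key=lambda t: t[0])
        run: list[tuple] = []
        for item in members:
            if run:
                prev_order, prev_meta, prev_read = run[-1]
                order, m, r = item
                linked = (
                    order == prev_order + 1
                    and r.chrom == prev_read.chrom
                    and r.strand == prev_read.strand
                    and _gap(prev_read, r) <= max_gap
                )
                if linked and max_time_gap is not None:
                    if m.start_time is None or prev_meta.start_time is None:
                        linked = False
                    else:
                        linked = (m.start_time - prev_meta.start_time) <= max_time_gap
                if not linked:
                    if len(run) >= 2:
                        chains.append(_make_chain(run))
                    run = []
            run.append(item)
        if len(run) >= 2:
            chains.append(_make_chain(run))
    report = {"n_reads": len(reads), "n_without_metadata": len(missing),
              "n_chains": len(chains)}
    return chains, report


def _make_chain(run: list[tuple]) -> OversplitChain:
    reads = [r for _, _, r in run]
    strand = reads[0].strand
    if strand == "+":
        best = max(run, key=lambda t: (t[2].end, t[0]))
    else:
        best = max(run, key=lambda t: (-t[2].start, t[0]))
    return OversplitChain(
        read_ids=tuple(r.read_id for r in reads),
        chrom=reads[0].chrom,
        strand=strand,
        kept_read_id=best[2].read_id,
    )


def apply_oversplit_filter(
    reads: Sequence[AlignedRead],
    chains: Sequence[OversplitChain],
) -> tuple[list[AlignedRead], dict]:
    """Drop all chain members except the kept (most-3') read."""
    removed = set()
    histogram: dict[int, int] = {}
    for chain in chains:
        histogram[len(chain.read_ids)] = histogram.get(len(chain.read_ids), 0) + 1
        removed.update(set(chain.read_ids) - {chain.kept_read_id})
    retained = [r for r in reads if r.read_id not in removed]
    report = {
        "n_input": len(reads),
        "n_removed": len(reads) - len(retained),
        "n_retained": len(retained),
        "chain_length_histogram": dict(sorted(histogram.items())),
    }
    return retained, report
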