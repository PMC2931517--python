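"""Feature dotplot: visual comparison of two feature architectures.

The feature dotplot extends the classical dotplot to the feature level.
The query protein runs along the x-axis and the subject along the
y-axis.  Every feature shared by the two proteins appears as one
diagonal segment per (query-instance, subject-instance) pair, drawn from
(q_start, p_start) to (q_end, p_end); the slope of the segment is the
length ratio of the two instances (inclusive-coordinate lengths).
Features present in only one protein are marked along the corresponding
axis margin.  A word-match amino-acid dotplot can be embedded when both
sequences are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, IO, Iterable, List, Optional, Sequence, Set, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .architecture_model import FeatureArchitecture

__all__ = [
    "FeatureSegment",
    "SequenceDot",
    "build_feature_segments",
    "build_sequence_dots",
    "render_dotplot",
    "write_segments_tsv",
]


@dataclass(frozen=True)
class FeatureSegment:
    """One diagonal for a (query instance, subject instance) pair."""

    feature_id: str
    q_start: int
    q_end: int
    p_start: int
    p_end: int

    @property
    def slope(self) -> float:
        """Subject instance length over query instance length (inclusive)."""
        return (self.p_end - self.p_start + 1) / (self.q_end - self.q_start + 1)


@dataclass(frozen=True)
class SequenceDot:
    """An exact w-residue word match at (x, y), 1-based."""

    x: int
    y: int
    word_size: int


def build_feature_segments(
    q: FeatureArchitecture, p: FeatureArchitecture
) -> List[FeatureSegment]:
    """Segments for every shared feature: the full instance cross-product.

    Ordered by feature id, then query start, then subject start, so the
    output is deterministic and dumps byte-identically.
    """
    shared = q.feature_ids & p.feature_ids
    segments: List[FeatureSegment] = []
    for feature_id in sorted(shared):
        q_insts = sorted(
            (i for i in q.instances if i.feature_id == feature_id),
            key=lambda i: (i.start, i.end),
        )
        p_insts = sorted(
            (i for i in p.instances if i.feature_id == feature_id),
            key=lambda i: (i.start, i.end),
        )
        for qi in q_insts:
            for pi in p_insts:
                segments.append(
                    FeatureSegment(feature_id, qi.start, qi.end, pi.start, pi.end)
                )
    return segments


def build_sequence_dots(
    q_seq: Optional[str], p_seq: Optional[str], w: int = 3
) -> List[SequenceDot]:
    """All positions where the two sequences share an exact w-mer.

    Empty when ``w`` exceeds either sequence length.  Both sequences must
    be present — supply them via FASTA.
    """
    if not q_seq or not p_seq:
        raise ValueError(
            "both sequences are required for the amino-acid dotplot; "
            "supply them via FASTA"
        )
    if w < 1:
        raise ValueError("word size must be >= 1")
    # index subject w-mers, then stream over query w-mers
    p_index: Dict[str, List[int]] = {}
    for y in range(len(p_seq) - w + 1):
        p_index.setdefault(p_seq[y : y + w], []).append(y + 1)
    dots: List[SequenceDot] = []
    for x in range(len(q_seq) - w + 1):
        for y in p_index.get(q_seq[x : x + w], ()):
            dots.append(SequenceDot(x + 1, y, w))
    return dots


# stable color cycle keyed by feature order
_COLOR_CYCLE = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def render_dotplot(
    q: FeatureArchitecture,
    p: FeatureArchitecture,
    segments: Sequence[FeatureSegment],
    dots: Sequence[SequenceDot] = (),
    out_path: str = "dotplot.svg",
    hide: Iterable[str] = (),
    title: Optional[str] = None,
) -> str:
    """Render the feature dotplot to SVG or PNG (by file extension).

    Shared features are coloured diagonals; features unique to one
    protein are tick marks on that protein's axis margin; word matches
    are grey dots.  Features listed in ``hide`` are omitted entirely.
    """
    fmt = out_path.rsplit(".", 1)[-1].lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported output format {fmt!r}; use svg or png")
    hidden: Set[str] = set(hide)

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.set_xlim(0, q.length + 1)
    ax.set_ylim(0, p.length + 1)
    ax.set_xlabel(f"{q.protein_id} (query, {q.length} aa)")
    ax.set_ylabel(f"{p.protein_id} (subject, {p.length} aa)")
    if title:
        ax.set_title(title)

    if dots:
        ax.scatter(
            [d.x for d in dots],
            [d.y for d in dots],
            s=2,
            c="0.6",
            marker=".",
            linewidths=0,
            zorder=1,
            label=f"{dots[0].word_size}-mer matches" if dots else None,
        )

    shown = sorted({s.feature_id for s in segments} - hidden)
    color_of = {f: _COLOR_CYCLE[i % len(_COLOR_CYCLE)] for i, f in enumerate(shown)}
    seen_label: Set[str] = set()
    for seg in segments:
        if seg.feature_id in hidden:
            continue
        label = None if seg.feature_id in seen_label else seg.feature_id
        seen_label.add(seg.feature_id)
        ax.plot(
            [seg.q_start, seg.q_end],
            [seg.p_start, seg.p_end],
            color=color_of[seg.feature_id],
            lw=2,
            zorder=2,
            label=label,
        )

    shared = q.feature_ids & p.feature_ids
    for inst in q.instances:  # query-only features: x-axis margin marks
        if inst.feature_id in shared or inst.feature_id in hidden:
            continue
        ax.plot(
            [inst.start, inst.end],
            [0, 0],
            color="0.2",
            lw=4,
            solid_capstyle="butt",
            zorder=3,
        )
        ax.annotate(
            inst.feature_id,
            ((inst.start + inst.end) / 2, 0),
            xytext=(0, 4),
            textcoords="offset points",
            ha="center",
            fontsize=7,
        )
    for inst in p.instances:  # subject-only features: y-axis margin marks
        if inst.feature_id in shared or inst.feature_id in hidden:
            continue
        ax.plot(
            [0, 0],
            [inst.start, inst.end],
            color="0.2",
            lw=4,
            solid_capstyle="butt",
            zorder=3,
        )
        ax.annotate(
            inst.feature_id,
            (0, (inst.start + inst.end) / 2),
            xytext=(4, 0),
            textcoords="offset points",
            va="center",
            rotation=90,
            fontsize=7,
        )

    if shown or dots:
        ax.legend(loc="upper left", fontsize=7, framealpha=0.8)
    fig.tight_layout()
    fig.savefig(out_path, format=fmt)
    plt.close(fig)
    return out_path


def write_segments_tsv(
    segments: Sequence[FeatureSegment],
    dots: Sequence[SequenceDot],
    sink: IO[str],
) -> None:
    """Plain-text dump of segments and dots; bit-exact across runs."""
    sink.write("# kind\tfeature_id\tq_start\tq_end\tp_start\tp_end\tslope\n")
    for s in segments:
        sink.write(
            f"segment\t{s.feature_id}\t{s.q_start}\t{s.q_end}\t{s.p_start}\t"
            f"{s.p_end}\t{s.slope:.6f}\n"
        )
    sink.write("# kind\tx\ty\tword_size\n")
    for d in dots:
        sink.write(f"dot\t{d.x}\t{d.y}\t{d.word_size}\n")
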