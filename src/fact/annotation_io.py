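"""Readers and writers for architectures and the standard external formats.

The interchange format is a pair of tab-separated files:

* proteins table — ``protein_id<TAB>length``, one row per protein.  A
  protein with no annotated features appears only here, so featureless
  proteins remain representable and scoreable.
* features table — ``protein_id<TAB>feature_id<TAB>start<TAB>end``, one
  row per feature instance, 1-based inclusive coordinates.

``#`` starts a comment line in every text format handled here; all I/O is
UTF-8 with tab delimiters.  Dedicated importers exist for HMMER's
per-domain tabular output (``--domtblout``), the Pfam clans file, FASTA
and BLAST tabular (outfmt 6).  Raw outputs of SignalP/TMHMM/COILS/seg are
not parsed — convert them to the interchange TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, IO, Iterator, List, Optional, Tuple
import logging

from Bio import SeqIO

from .architecture_model import (
    FeatureArchitecture,
    FeatureCatalog,
    FeatureInstance,
    strip_version,
    validate_architecture,
)

__all__ = [
    "FormatError",
    "Proteome",
    "HitTable",
    "read_proteins_table",
    "read_features_table",
    "write_architecture_tables",
    "import_hmmer_domains",
    "read_clan_table",
    "read_fasta",
    "read_hit_table",
    "read_ec_map",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


class Proteome:
    """Ordered collection of architectures keyed by unique protein id.

    Maintains aggregate per-feature instance totals over all members —
    the reference-set counts the proteome-frequency weighting scheme
    needs.  Totals are updated on every mutation.
    """

    def __init__(self, archs: Iterable[FeatureArchitecture] = ()) -> None:
        self._archs: Dict[str, FeatureArchitecture] = {}
        self._feature_totals: Dict[str, int] = {}
        for arch in archs:
            self.add(arch)

    def add(self, arch: FeatureArchitecture) -> None:
        if arch.protein_id in self._archs:
            raise ValueError(f"duplicate protein_id {arch.protein_id!r}")
        self._archs[arch.protein_id] = arch
        for inst in arch.instances:
            self._feature_totals[inst.feature_id] = (
                self._feature_totals.get(inst.feature_id, 0) + 1
            )

    def remove(self, protein_id: str) -> FeatureArchitecture:
        arch = self._archs.pop(protein_id)
        for inst in arch.instances:
            self._feature_totals[inst.feature_id] -= 1
            if self._feature_totals[inst.feature_id] == 0:
                del self._feature_totals[inst.feature_id]
        return arch

    @property
    def feature_totals(self) -> Dict[str, int]:
        """Aggregate instance count of each feature over all members."""
        return dict(self._feature_totals)

    def feature_total(self, feature_id: str) -> int:
        return self._feature_totals.get(feature_id, 0)

    def __getitem__(self, protein_id: str) -> FeatureArchitecture:
        return self._archs[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._archs

    def __iter__(self) -> Iterator[FeatureArchitecture]:
        return iter(self._archs.values())

    def __len__(self) -> int:
        return len(self._archs)

    @property
    def protein_ids(self) -> List[str]:
        return list(self._archs)

    def __eq__(self, other) -> bool:
        return isinstance(other, Proteome) and self._archs == other._archs


@dataclass
class HitTable:
    """Best sequence-similarity hit per query, with its E-value."""

    best_hits: Dict[str, Tuple[str, float]] = field(default_factory=dict)

    def __getitem__(self, query_id: str) -> Tuple[str, float]:
        return self.best_hits[query_id]

    def __contains__(self, query_id: str) -> bool:
        return query_id in self.best_hits

    def __len__(self) -> int:
        return len(self.best_hits)


def _data_lines(source: IO[str]) -> Iterator[Tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def read_proteins_table(source: IO[str]) -> Dict[str, int]:
    """Parse the proteins table into ``{protein_id: length}``."""
    lengths: Dict[str, int] = {}
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
        pid, raw_len = fields[0], fields[1]
        if pid in lengths:
            raise FormatError(f"duplicate protein_id {pid} at line {lineno}")
        try:
            length = int(raw_len)
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-integer length {raw_len!r} for {pid}"
            ) from None
        if length <= 0:
            raise FormatError(f"line {lineno}: non-positive length for {pid}")
        lengths[pid] = length
    return lengths


def read_features_table(source: IO[str], lengths: Dict[str, int]) -> Proteome:
    """Parse the features table against known protein lengths.

    Proteins listed in ``lengths`` but absent from the features table are
    included with an empty instance list.
    """
    instances: Dict[str, List[FeatureInstance]] = {pid: [] for pid in lengths}
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: expected 4 tab-separated columns")
        pid, feature_id, raw_start, raw_end = fields[:4]
        if pid not in lengths:
            raise FormatError(f"line {lineno}: unknown protein_id {pid}")
        try:
            start, end = int(raw_start), int(raw_end)
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-integer coordinates for {pid}"
            ) from None
        if not (1 <= start <= end <= lengths[pid]):
            raise FormatError(
                f"line {lineno}: instance [{start},{end}] violates bounds of "
                f"{pid} (length {lengths[pid]})"
            )
        instances[pid].append(FeatureInstance(feature_id, start, end))
    proteome = Proteome(
        FeatureArchitecture(pid, lengths[pid], instances[pid]) for pid in lengths
    )
    for arch in proteome:
        bad = validate_architecture(arch)
        if bad:  # defensive: bounds were already checked per line
            raise FormatError("; ".join(bad))
    return proteome


def write_architecture_tables(
    proteome: Proteome, proteins_sink: IO[str], features_sink: IO[str]
) -> None:
    """Write the interchange pair; reading it back reproduces the proteome.

    Rows are ordered by protein id, then instance start, so repeated runs
    produce identical bytes.
    """
    proteins_sink.write("# protein_id\tlength\n")
    features_sink.write("# protein_id\tfeature_id\tstart\tend\n")
    for pid in sorted(p.protein_id for p in proteome):
        arch = proteome[pid]
        proteins_sink.write(f"{pid}\t{arch.length}\n")
        for inst in sorted(arch.instances, key=lambda i: (i.start, i.end, i.feature_id)):
            features_sink.write(
                f"{pid}\t{inst.feature_id}\t{inst.start}\t{inst.end}\n"
            )


# HMMER --domtblout column indices (whitespace-delimited):
# 0 target name, 1 target accession, 3 query name, 19 env from, 20 env to.
_DOMTBL_MIN_FIELDS = 22


def import_hmmer_domains(
    domtbl: IO[str], namespace: str, lengths: Dict[str, int]
) -> List[Tuple[str, FeatureInstance]]:
    """Import domain hits from HMMER3 per-domain tabular output.

    One instance per domain-hit row; the feature id is
    ``namespace:accession`` with the version suffix stripped, falling back
    to the model name when the accession column is ``-``.  Envelope
    coordinates (not alignment coordinates) define the instance, since
    the envelope bounds the full domain placement.  Rows for proteins
    absent from ``lengths`` are skipped with a warning.
    """
    out: List[Tuple[str, FeatureInstance]] = []
    for lineno, line in _data_lines(domtbl):
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise FormatError(
                f"line {lineno}: expected ≥{_DOMTBL_MIN_FIELDS} fields in "
                f"domtblout row, got {len(fields)}"
            )
        model_name, accession, protein_id = fields[0], fields[1], fields[3]
        if accession == "-":
            accession = model_name
        feature_id = f"{namespace}:{strip_version(accession)}"
        try:
            env_from, env_to = int(fields[19]), int(fields[20])
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-integer envelope coordinates"
            ) from None
        if protein_id not in lengths:
            logger.warning(
                "domtblout line %d: protein %s not in lengths table, skipped",
                lineno,
                protein_id,
            )
            continue
        out.append((protein_id, FeatureInstance(feature_id, env_from, env_to)))
    return out


def read_clan_table(
    source: IO[str], pfam_namespace: str = "pfam"
) -> FeatureCatalog:
    """Parse a Pfam accession → clan accession table.

    Accepts a minimal two-column TSV or the official five-column clans
    file (extra columns ignored).  An empty clan field means "no clan".
    """
    clan_of: Dict[str, str] = {}
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        acc = strip_version(fields[0].strip())
        clan = fields[1].strip() if len(fields) > 1 else ""
        if not acc:
            raise FormatError(f"line {lineno}: empty accession")
        key = f"{pfam_namespace}:{acc}"
        if not clan:
            continue
        if key in clan_of and clan_of[key] != clan:
            raise FormatError(
                f"line {lineno}: accession {acc} mapped to conflicting clans "
                f"{clan_of[key]} and {clan}"
            )
        clan_of[key] = clan
    return FeatureCatalog(clan_of, pfam_namespaces={pfam_namespace})


def read_fasta(source: IO[str]) -> Dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}``; ids must be unique."""
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(source, "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence id {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id}")
        sequences[record.id] = seq
    return sequences


def read_hit_table(source: IO[str]) -> HitTable:
    """Parse BLAST tabular output (outfmt 6), keeping each query's best hit.

    The best hit is the row with the smallest E-value (first occurrence
    wins ties).  An E-value of exactly 0.0 is kept as 0.0; downstream
    binning places it in the smallest bin.
    """
    best: Dict[str, Tuple[str, float]] = {}
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, got "
                f"{len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-numeric E-value {fields[10]!r}"
            ) from None
        if evalue < 0 or math.isnan(evalue):
            raise FormatError(f"line {lineno}: invalid E-value {evalue}")
        if query not in best or evalue < best[query][1]:
            best[query] = (subject, evalue)
    return HitTable(best)


def read_ec_map(source: IO[str]) -> Dict[str, str]:
    """Parse ``protein_id<TAB>EC`` rows; EC codes have four dotted fields."""
    ec: Dict[str, str] = {}
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
        pid, code = fields[0], fields[1].strip()
        if len(code.split(".")) != 4:
            raise FormatError(
                f"line {lineno}: EC code {code!r} does not have 4 dotted fields"
            )
        if pid in ec:
            raise FormatError(f"duplicate protein_id {pid} at line {lineno}")
        ec[pid] = code
    return ec
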