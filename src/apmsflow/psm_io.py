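"""PSM/protein data model, standard-format readers and tryptic digestion.

Coordinates are 1-based inclusive throughout. Peptide-to-protein mapping is
exact substring matching with I and L treated as distinct letters, since
search engines emit database-resolved sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from apmsflow.errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters; B/J/O/U/X/Z are rejected.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average isotopic residue masses (Da), for whole-protein mass estimates.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
AVERAGE_WATER_MASS = 18.01528

PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "modifications",
    "charge",
    "intensity",
    "sample_id",
    "band",
    "condition",
    "replicate",
    "q_value",
    "e_value",
)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry with a canonical-alphabet sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"protein {self.accession!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))} (only the 20 canonical letters are accepted)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with intensity and sample labels.

    ``modifications`` is a tuple of ``(position, mass_delta)`` pairs where
    position is a 1-based residue index within the peptide and the delta is
    in Daltons. ``intensity`` is the summed MS2 fragment-ion intensity of
    the matched spectrum (arbitrary units).
    """

    spectrum_id: str
    peptide: str
    modifications: tuple[tuple[int, float], ...]
    charge: int
    intensity: float
    sample_id: str
    band: str
    condition: str
    replicate: int
    q_value: float
    e_value: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(f"PSM {self.spectrum_id!r}: negative intensity")
        for pos, _ in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise ValidationError(
                    f"PSM {self.spectrum_id!r}: modification position {pos} "
                    f"outside peptide of length {len(self.peptide)}"
                )


@dataclass
class PeptideProteinMap:
    """Peptide → protein placements with per-peptide uniqueness flags.

    ``spans[pep]`` lists ``(accession, start, end)`` with 1-based inclusive
    coordinates; ``unique[pep]`` is True iff the peptide matched exactly one
    accession (possibly at several positions within it).
    """

    spans: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    unique: dict[str, bool] = field(default_factory=dict)

    def accessions_for(self, peptide: str) -> list[str]:
        seen: list[str] = []
        for acc, _, _ in self.spans.get(peptide, []):
            if acc not in seen:
                seen.append(acc)
        return seen

    def unique_accession(self, peptide: str) -> str | None:
        """The single accession a peptide maps to, or None if shared/unmapped."""
        if self.unique.get(peptide):
            return self.spans[peptide][0][0]
        return None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, order preserved.

    Sequences are upper-cased and whitespace-stripped. A record with an
    empty sequence or a non-canonical residue raises :class:`ParseError`
    naming the record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        accession = seq_record.id
        description = seq_record.description[len(accession):].strip()
        sequence = str(seq_record.seq).upper().replace(" ", "").replace("\t", "")
        try:
            records.append(ProteinRecord(accession, description, sequence))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def _parse_modifications(text: str, line_no: int) -> tuple[tuple[int, float], ...]:
    text = text.strip()
    if not text:
        return ()
    mods: list[tuple[int, float]] = []
    for chunk in text.split(";"):
        try:
            pos_s, delta_s = chunk.split(":")
            mods.append((int(pos_s), float(delta_s)))
        except ValueError as exc:
            raise ParseError(
                f"line {line_no}: malformed modification field {text!r} "
                "(expected 'pos:delta[;pos:delta]*')"
            ) from exc
    return tuple(mods)


def read_psm_table(path: str | Path, q_value_max: float = 0.01) -> list[PSMRecord]:
    """Read the tab-separated PSM dialect, applying the q-value input filter.

    Rows with ``q_value > q_value_max`` are excluded and the exclusion count
    is logged. Missing required columns raise :class:`SchemaError`; a
    non-numeric field raises :class:`ParseError` with its line number.
    """
    path = Path(path)
    with path.open() as handle:
        header_line = handle.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}
        records: list[PSMRecord] = []
        n_excluded = 0
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise ParseError(f"{path}: line {line_no}: expected {len(header)} fields, got {len(fields)}")

            def _num(col: str, cast, *, _fields=fields, _line_no=line_no):
                raw = _fields[idx[col]]
                try:
                    return cast(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {_line_no}: non-numeric {col} value {raw!r}"
                    ) from exc

            q_value = _num("q_value", float)
            record = PSMRecord(
                spectrum_id=fields[idx["spectrum_id"]],
                peptide=fields[idx["peptide"]],
                modifications=_parse_modifications(fields[idx["modifications"]], line_no),
                charge=_num("charge", int),
                intensity=_num("intensity", float),
                sample_id=fields[idx["sample_id"]],
                band=fields[idx["band"]],
                condition=fields[idx["condition"]],
                replicate=_num("replicate", int),
                q_value=q_value,
                e_value=_num("e_value", float),
            )
            if q_value > q_value_max:
                n_excluded += 1
                continue
            records.append(record)
    if n_excluded:
        logger.info("%s: excluded %d PSM(s) above q-value threshold %g", path, n_excluded, q_value_max)
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    """Write PSMs in the tab-separated dialect read by :func:`read_psm_table`.

    Floats are written with :func:`repr` so valid records round-trip
    bit-identically; modification deltas use 4 decimals per the dialect.
    """
    path = Path(path)
    with path.open("w") as handle:
        handle.write("\t".join(PSM_COLUMNS) + "\n")
        for rec in records:
            mods = ";".join(f"{pos}:{delta:.4f}" for pos, delta in rec.modifications)
            handle.write(
                "\t".join(
                    [
                        rec.spectrum_id,
                        rec.peptide,
                        mods,
                        str(rec.charge),
                        repr(rec.intensity),
                        rec.sample_id,
                        rec.band,
                        rec.condition,
                        str(rec.replicate),
                        repr(rec.q_value),
                        repr(rec.e_value),
                    ]
                )
                + "\n"
            )


def map_peptides(
    peptides: Iterable[str] | Iterable[PSMRecord],
    proteins: Sequence[ProteinRecord],
) -> PeptideProteinMap:
    """Place each peptide in every protein by exact substring matching.

    All occurrences are recorded; the uniqueness flag is True iff exactly
    one accession matched. Unmapped peptides get an empty span list, a
    False flag, and a logged warning.
    """
    if not proteins:
        raise ValidationError("map_peptides: protein list is empty")
    pep_set: list[str] = []
    seen: set[str] = set()
    for item in peptides:
        pep = item.peptide if isinstance(item, PSMRecord) else item
        if pep not in seen:
            seen.add(pep)
            pep_set.append(pep)
    pmap = PeptideProteinMap()
    if not pep_set:
        return pmap
    # seed-and-extend: bucket peptides by a short prefix, scan each protein once
    k = min(6, min(len(p) for p in pep_set))
    buckets: dict[str, list[str]] = {}
    for pep in pep_set:
        buckets.setdefault(pep[:k], []).append(pep)
    spans_by_pep: dict[str, list[tuple[str, int, int]]] = {pep: [] for pep in pep_set}
    for prot in proteins:
        seq = prot.sequence
        acc = prot.accession
        for i in range(len(seq) - k + 1):
            candidates = buckets.get(seq[i : i + k])
            if candidates is None:
                continue
            for pep in candidates:
                if seq.startswith(pep, i):
                    spans_by_pep[pep].append((acc, i + 1, i + len(pep)))
    for pep in pep_set:
        spans = spans_by_pep[pep]
        pmap.spans[pep] = spans
        accessions = {acc for acc, _, _ in spans}
        pmap.unique[pep] = len(accessions) == 1
        if not spans:
            logger.warning("peptide %r matched no protein in the database", pep)
    return pmap


def protein_average_mass(sequence: str) -> float:
    """Average-isotopic molecular mass in Daltons: residue masses + one water."""
    try:
        return sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + AVERAGE_WATER_MASS
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}") from exc


def digest(
    sequence: str,
    missed_cleavages: int | None = None,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digestion: cleave after K/R unless followed by P.

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive spans,
    retaining peptides with 0..``missed_cleavages`` internal retained sites
    (``None`` = no limit) and lengths within ``[min_len, max_len]``.
    """
    if max_len is not None and min_len > max_len:
        raise ValidationError(f"digest: min_len {min_len} > max_len {max_len}")
    n = len(sequence)
    # cut points: index i means a cleavage between residue i and i+1 (0-based)
    cuts = [0]
    for i in range(n - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(n)
    n_frag = len(cuts) - 1
    limit = n_frag if missed_cleavages is None else missed_cleavages + 1
    peptides: list[tuple[str, int, int]] = []
    for i in range(n_frag):
        for j in range(i + 1, min(i + 1 + limit, n_frag + 1)):
            start, end = cuts[i], cuts[j]
            length = end - start
            if length < min_len or (max_len is not None and length > max_len):
                continue
            peptides.append((sequence[start:end], start + 1, end))
    return peptides
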