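"""Peptide counts, spectral index (SI and SI_GI) and sequence coverage.

SI_GI is implemented as a protein's share of the summed retained PSM
intensity within one sample: SI(p, s) is the sum of intensities of PSMs in
sample s whose peptide maps uniquely to p, and SI_GI(p, s) = SI(p, s)
divided by the global intensity of s (summed over *all* retained PSMs,
including shared-peptide ones). No protein-length normalization is applied.
Shared-peptide PSMs therefore count toward every denominator but no
numerator, avoiding double counting.

Proteins with fewer than two distinct (uniquely mapping) peptides are
zeroed; the granularity of that rule — across a band's whole replicate set
(default) or per sample — is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from apmsflow.errors import ValidationError
from apmsflow.psm_io import PSMRecord, PeptideProteinMap, ProteinRecord


def sample_label(band: str, condition: str, replicate: int) -> str:
    return f"{band}|{condition}|r{replicate}"


def split_sample_label(label: str) -> tuple[str, str, int]:
    band, condition, rep = label.split("|")
    return band, condition, int(rep.lstrip("r"))


@dataclass
class QuantMatrix:
    """Proteins × samples table of SI_GI values plus peptide counts.

    ``samples`` are labels of the form ``band|condition|r<replicate>``;
    ``values`` and ``peptide_counts`` are aligned arrays of shape
    (n_proteins, n_samples).
    """

    proteins: list[str]
    samples: list[str]
    values: np.ndarray
    peptide_counts: np.ndarray
    low_evidence: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peptide_counts = np.asarray(self.peptide_counts, dtype=int)
        expected = (len(self.proteins), len(self.samples))
        if self.values.shape != expected or self.peptide_counts.shape != expected:
            raise ValidationError(f"QuantMatrix: shape mismatch, expected {expected}")
        if (self.values < 0).any():
            raise ValidationError("QuantMatrix: negative SI_GI value")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.samples)

    def value(self, protein: str, sample: str) -> float:
        return float(self.values[self.proteins.index(protein), self.samples.index(sample)])

    def band_samples(self, band: str, condition: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            b, c, _ = split_sample_label(s)
            if b == band and (condition is None or c == condition):
                out.append(s)
        return out

    def bands(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            b, _, _ = split_sample_label(s)
            if b not in seen:
                seen.append(b)
        return seen

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "accession"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            proteins=list(df.index),
            samples=list(df.columns),
            values=df.to_numpy(dtype=float),
            peptide_counts=np.zeros(df.shape, dtype=int),
        )


@dataclass
class CoverageReport:
    """Per-residue coverage of one protein plus optional region breakdowns."""

    accession: str
    covered_mask: np.ndarray
    coverage_percent: float
    region_coverage: list[tuple[str, int, int, float]] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("accession\tregion\tstart\tend\tpercent\n")
            n = len(self.covered_mask)
            handle.write(f"{self.accession}\tfull\t1\t{n}\t{self.coverage_percent:.2f}\n")
            for label, start, end, pct in self.region_coverage:
                handle.write(f"{self.accession}\t{label}\t{start}\t{end}\t{pct:.2f}\n")


def spectral_index(
    psms: Iterable[PSMRecord],
    accession: str,
    pmap: PeptideProteinMap,
    known_accessions: set[str] | None = None,
) -> float:
    """Sum of PSM intensities whose peptide maps uniquely to ``accession``.

    Shared-peptide PSMs contribute to no protein's SI. Zero when no PSMs
    match. Raises for an accession absent from ``known_accessions`` when
    that set is provided.
    """
    if known_accessions is not None and accession not in known_accessions:
        raise ValidationError(f"spectral_index: unknown accession {accession!r}")
    total = 0.0
    for psm in psms:
        if pmap.unique_accession(psm.peptide) == accession:
            total += psm.intensity
    return total


def _group_by_sample(psms: Iterable[PSMRecord]) -> dict[str, list[PSMRecord]]:
    groups: dict[str, list[PSMRecord]] = {}
    for psm in psms:
        label = sample_label(psm.band, psm.condition, psm.replicate)
        groups.setdefault(label, []).append(psm)
    return groups


def si_gi_matrix(
    psms: Iterable[PSMRecord],
    proteins: Sequence[ProteinRecord] | Sequence[str],
    pmap: PeptideProteinMap,
    min_peptides: int = 2,
    min_peptides_granularity: str = "band",
) -> QuantMatrix:
    """Build the SI_GI QuantMatrix over all samples present in ``psms``.

    The global denominator of each sample is the sum over all its retained
    PSMs (including shared-peptide PSMs). Proteins with fewer than
    ``min_peptides`` distinct uniquely-mapping peptides — counted across the
    band's replicate set (``granularity="band"``, default) or per sample —
    are zeroed for the affected samples and flagged in ``low_evidence``.
    """
    if min_peptides_granularity not in ("band", "sample"):
        raise ValidationError(
            f"min_peptides_granularity must be 'band' or 'sample', got {min_peptides_granularity!r}"
        )
    accessions = [p.accession if isinstance(p, ProteinRecord) else p for p in proteins]
    acc_index = {acc: i for i, acc in enumerate(accessions)}
    by_sample = _group_by_sample(psms)
    samples = sorted(by_sample, key=lambda s: (split_sample_label(s)[0], split_sample_label(s)[1], split_sample_label(s)[2]))

    values = np.zeros((len(accessions), len(samples)))
    counts = np.zeros((len(accessions), len(samples)), dtype=int)
    # distinct unique peptides per (protein, sample) and per (protein, band)
    sample_peps: dict[tuple[str, str], set[str]] = {}
    band_peps: dict[tuple[str, str], set[str]] = {}

    for j, label in enumerate(samples):
        band, _, _ = split_sample_label(label)
        global_intensity = sum(p.intensity for p in by_sample[label])
        if global_intensity <= 0:
            raise ValidationError(f"sample {label!r}: zero total intensity")
        for psm in by_sample[label]:
            acc = pmap.unique_accession(psm.peptide)
            if acc is None or acc not in acc_index:
                continue
            values[acc_index[acc], j] += psm.intensity
            sample_peps.setdefault((acc, label), set()).add(psm.peptide)
            band_peps.setdefault((acc, band), set()).add(psm.peptide)
        values[:, j] /= global_intensity

    low_evidence: set[tuple[str, str]] = set()
    for j, label in enumerate(samples):
        band, _, _ = split_sample_label(label)
        for acc, i in acc_index.items():
            n_sample = len(sample_peps.get((acc, label), ()))
            counts[i, j] = n_sample
            n_scope = (
                len(band_peps.get((acc, band), ()))
                if min_peptides_granularity == "band"
                else n_sample
            )
            if values[i, j] > 0 and n_scope < min_peptides:
                values[i, j] = 0.0
                low_evidence.add((acc, label))

    return QuantMatrix(accessions, samples, values, counts, low_evidence)


def sequence_coverage(
    peptides: Iterable[str],
    protein: ProteinRecord,
    pmap: PeptideProteinMap,
    regions: Sequence[tuple[str, int, int]] = (),
) -> CoverageReport:
    """Residue coverage of ``protein`` by the mapped spans of ``peptides``.

    A residue is covered iff it lies inside at least one mapped span of a
    listed peptide. Percentages are reported to 2 decimals; region percents
    are computed only over each region's residues.
    """
    n = len(protein.sequence)
    mask = np.zeros(n, dtype=bool)
    for pep in peptides:
        for acc, start, end in pmap.spans.get(pep, []):
            if acc == protein.accession:
                mask[start - 1 : end] = True
    percent = round(100.0 * mask.sum() / n, 2)
    region_cov: list[tuple[str, int, int, float]] = []
    for label, start, end in regions:
        if not (1 <= start <= end <= n):
            raise ValidationError(
                f"region {label!r} ({start}-{end}) outside sequence bounds 1-{n}"
            )
        sub = mask[start - 1 : end]
        region_cov.append((label, start, end, round(100.0 * sub.sum() / len(sub), 2)))
    return CoverageReport(protein.accession, mask, percent, region_cov)
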