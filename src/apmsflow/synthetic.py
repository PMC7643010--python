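"""Synthetic fixtures: toy proteome, planted AP-MS experiment, and
phosphopeptide fragment spectra with planted sites.

Everything is a pure function of (design, seed): identical designs produce
byte-identical FASTA/TSV/MGF output. Intensities are log-normal (heavy
tailed like real fragment intensities); the bait and its planted partners
are multiplied by an enrichment fold in bait samples only, while background
binders have equal expectation in both conditions — the statistical shape
of an IgG-bead background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from apmsflow.errors import ValidationError
from apmsflow.phospho import (
    FragmentSpectrum,
    PHOSPHO_DELTA,
    PROTON,
    RESIDUE_MASS,
    WATER,
    theoretical_ions,
    write_mgf,
)
from apmsflow.psm_io import PSMRecord, ProteinRecord, digest, write_fasta, write_psm_table

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PhosphoDesign:
    n_spectra: int = 200
    noise_peaks_per_window: int = 20
    n_true_sites: int = 8


@dataclass
class SimulationDesign:
    seed: int = 0
    n_background: int = 60
    n_partners: int = 12
    bands: tuple[str, ...] = ("300kDa", "600kDa", "800kDa")
    n_replicates: int = 4
    bait_enrichment_fold: float = 8.0
    bait_abundance_boost: float = 4.0
    intensity_logmean: float = 12.0
    intensity_logsd: float = 1.0
    dropout_prob: float = 0.1
    peptides_per_protein: int = 50
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    phospho: PhosphoDesign = field(default_factory=PhosphoDesign)

    def __post_init__(self) -> None:
        if isinstance(self.phospho, dict):
            self.phospho = PhosphoDesign(**self.phospho)
        if self.n_background <= 0 or self.n_partners <= 0 or self.n_replicates <= 0:
            raise ValidationError("design counts must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")


@dataclass
class GroundTruth:
    bait_accession: str = ""
    partners_by_band: dict[str, list[str]] = field(default_factory=dict)
    background: list[str] = field(default_factory=list)
    evidence_edges: list[tuple[str, str, int, int]] = field(default_factory=list)
    true_sites: list[tuple[str, int]] = field(default_factory=list)

    def all_partners(self) -> set[str]:
        return {p for members in self.partners_by_band.values() for p in members}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["evidence_edges"] = [tuple(e) for e in payload["evidence_edges"]]
        payload["true_sites"] = [tuple(s) for s in payload["true_sites"]]
        return cls(**payload)


def _aa_probabilities() -> np.ndarray:
    """Residue frequencies with K/R elevated so tryptic peptides average
    ~8-9 residues (mostly inside the 6-40 window)."""
    probs = np.full(20, (1.0 - 0.12) / 18)
    probs[AA_ORDER.index("K")] = 0.06
    probs[AA_ORDER.index("R")] = 0.06
    return probs


def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AA_ORDER[i] for i in idx)


def generate_proteome(design: SimulationDesign) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random canonical-alphabet proteome: one bait, planted partners and
    background binders. Deterministic given the design seed; every sequence
    is guaranteed to yield at least one tryptic peptide of the configured
    length range."""
    rng = np.random.default_rng(design.seed)
    probs = _aa_probabilities()

    def make(accession: str, description: str, length: int) -> ProteinRecord:
        for _ in range(100):
            seq = _random_sequence(rng, length, probs)
            peptides = digest(seq, 0, design.min_peptide_len, design.max_peptide_len)
            if peptides:
                return ProteinRecord(accession, description, seq)
        raise ValidationError(f"could not generate a digestible sequence for {accession}")

    records = [make("BAIT001", "planted bait protein", 1100)]
    for i in range(design.n_partners):
        length = int(rng.integers(100, 1201))
        records.append(make(f"PART{i + 1:03d}", "planted partner", length))
    for i in range(design.n_background):
        length = int(rng.integers(100, 1201))
        records.append(make(f"BKGD{i + 1:03d}", "background binder", length))

    truth = GroundTruth(
        bait_accession="BAIT001",
        background=[r.accession for r in records if r.accession.startswith("BKGD")],
    )
    # each partner joins a random non-empty subset of bands so band sets overlap
    partners = [r.accession for r in records if r.accession.startswith("PART")]
    truth.partners_by_band = {band: [] for band in design.bands}
    for acc in partners:
        member = rng.random(len(design.bands)) < 0.6
        if not member.any():
            member[int(rng.integers(len(design.bands)))] = True
        for band, m in zip(design.bands, member):
            if m:
                truth.partners_by_band[band].append(acc)
    # evidence edges chain partners together (plus a few random extras)
    for a, b in zip(partners, partners[1:]):
        truth.evidence_edges.append((a, b, int(rng.integers(750, 1001)), int(rng.integers(900, 1001))))
    for _ in range(design.n_partners // 2):
        i, j = rng.choice(len(partners), size=2, replace=False)
        a, b = sorted((partners[i], partners[j]))
        if (a, b) not in {(x, y) for x, y, _, _ in truth.evidence_edges}:
            truth.evidence_edges.append((a, b, int(rng.integers(750, 1001)), int(rng.integers(900, 1001))))
    return records, truth


def _protein_peptides(design: SimulationDesign, record: ProteinRecord) -> list[str]:
    peptides = digest(record.sequence, 0, design.min_peptide_len, design.max_peptide_len)
    return [p for p, _, _ in peptides[: design.peptides_per_protein]]


def generate_apms(
    design: SimulationDesign,
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
) -> dict[tuple[str, str, int], list[PSMRecord]]:
    """PSM tables for every band × condition × replicate.

    Per-peptide intensities are log-normal draws; bait and partner peptides
    are multiplied by the enrichment fold in bait samples only (the bait by
    an additional abundance boost so it dominates every bait sample), and
    per-peptide dropout is applied independently.
    """
    rng = np.random.default_rng(design.seed + 1)
    by_acc = {r.accession: r for r in proteome}
    peptide_cache = {r.accession: _protein_peptides(design, r) for r in proteome}
    tables: dict[tuple[str, str, int], list[PSMRecord]] = {}
    for band in design.bands:
        band_proteins = [truth.bait_accession] + truth.partners_by_band[band] + truth.background
        for condition in ("bait", "control"):
            for rep in range(1, design.n_replicates + 1):
                sample_id = f"{band}_{condition}_r{rep}"
                records: list[PSMRecord] = []
                scan = 0
                for acc in band_proteins:
                    is_bait = acc == truth.bait_accession
                    is_partner = acc.startswith("PART")
                    factor = 1.0
                    if condition == "bait" and (is_bait or is_partner):
                        factor = design.bait_enrichment_fold
                        if is_bait:
                            factor *= design.bait_abundance_boost
                    for peptide in peptide_cache[acc]:
                        dropped = rng.random() < design.dropout_prob
                        intensity = factor * float(
                            np.exp(rng.normal(design.intensity_logmean, design.intensity_logsd))
                        )
                        if dropped:
                            continue
                        scan += 1
                        records.append(
                            PSMRecord(
                                spectrum_id=f"{sample_id}_scan{scan}",
                                peptide=peptide,
                                modifications=(),
                                charge=2,
                                intensity=round(intensity, 3),
                                sample_id=sample_id,
                                band=band,
                                condition=condition,
                                replicate=rep,
                                q_value=0.001,
                                e_value=1e-9,
                            )
                        )
                tables[(band, condition, rep)] = records
    # keep unused but deterministic: by_acc retained for future shaping hooks
    del by_acc
    return tables


def _peptide_mass(peptide: str, n_phospho: int) -> float:
    return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER + n_phospho * PHOSPHO_DELTA


def generate_phospho_spectra(
    design: SimulationDesign,
    proteome: Sequence[ProteinRecord],
    truth: GroundTruth,
    tolerance: float = 0.05,
) -> tuple[list[FragmentSpectrum], list[tuple[str, str, int, int]], GroundTruth]:
    """Fragment spectra encoding planted phosphosites on the bait.

    Each spectrum carries every singly charged b/y ion of the true
    phospho-isoform at high intensity plus low-intensity uniform noise
    peaks (``noise_peaks_per_window`` per 100 m/z window) that are kept
    clear of every candidate isoform's theoretical ions, so the planted
    site is recoverable by localization scoring.

    Returns ``(spectra, assignments, truth)`` where assignments rows are
    ``(spectrum_id, peptide, n_phospho, replicate)``; planted sites are
    appended to ``truth.true_sites`` as protein coordinates.
    """
    rng = np.random.default_rng(design.seed + 2)
    bait = next(r for r in proteome if r.accession == truth.bait_accession)
    candidates = [
        (pep, start)
        for pep, start, _ in digest(bait.sequence, 0, design.min_peptide_len, design.max_peptide_len)
        if sum(aa in "STY" for aa in pep) >= 2 and len(pep) <= 25
    ]
    if len(candidates) < design.phospho.n_true_sites:
        raise ValidationError(
            f"bait yields only {len(candidates)} phospho-capable peptides, "
            f"need {design.phospho.n_true_sites}"
        )
    pick = rng.choice(len(candidates), size=design.phospho.n_true_sites, replace=False)
    planted: list[tuple[str, int, int]] = []  # peptide, site-in-peptide, protein coord
    for idx in sorted(pick):
        pep, start = candidates[idx]
        sty = [i + 1 for i, aa in enumerate(pep) if aa in "STY"]
        site = int(sty[int(rng.integers(len(sty)))])
        planted.append((pep, site, start + site - 1))
        truth.true_sites.append((bait.accession, start + site - 1))

    spectra: list[FragmentSpectrum] = []
    assignments: list[tuple[str, str, int, int]] = []
    for i in range(design.phospho.n_spectra):
        pep, site, _coord = planted[i % len(planted)]
        replicate = (i % design.n_replicates) + 1
        iso = theoretical_ions(pep, {site})
        # every candidate isoform's ions form the noise exclusion zone
        sty = [j + 1 for j, aa in enumerate(pep) if aa in "STY"]
        forbidden = np.array(
            sorted(
                mz
                for pos in sty
                for _, _, mz in theoretical_ions(pep, {pos}).theoretical_ions
            )
        )
        peaks = [(mz, float(rng.uniform(500.0, 1000.0))) for _, _, mz in iso.theoretical_ions]
        max_mz = float(forbidden.max())
        n_windows = int(np.ceil(max_mz / 100.0))
        for w in range(n_windows):
            for _ in range(design.phospho.noise_peaks_per_window):
                for _try in range(50):
                    mz = float(rng.uniform(w * 100.0, (w + 1) * 100.0))
                    if np.abs(forbidden - mz).min() > 2.0 * tolerance:
                        peaks.append((mz, float(rng.uniform(5.0, 50.0))))
                        break
        spectrum_id = f"phospho_r{replicate}_scan{i + 1}"
        precursor = (_peptide_mass(pep, 1) + 2 * PROTON) / 2.0
        spectra.append(FragmentSpectrum(spectrum_id, round(precursor, 5), 2, np.array(peaks)))
        assignments.append((spectrum_id, pep, 1, replicate))
    return spectra, assignments, truth


# ---------------------------------------------------------------------------
# fixture emission


def write_assignments(assignments: Sequence[tuple[str, str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("spectrum_id\tpeptide\tn_phospho\treplicate\n")
        for spectrum_id, peptide, n_phospho, replicate in assignments:
            handle.write(f"{spectrum_id}\t{peptide}\t{n_phospho}\t{replicate}\n")


def read_assignments(path: str | Path) -> list[tuple[str, str, int, int]]:
    out: list[tuple[str, str, int, int]] = []
    with Path(path).open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["spectrum_id", "peptide", "n_phospho", "replicate"]:
            raise ValidationError(f"{path}: unexpected assignment header {header}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, pep, n, rep = line.split("\t")
            out.append((sid, pep, int(n), int(rep)))
    return out


def write_evidence_file(edges: Sequence[tuple[str, str, int, int]], path: str | Path) -> None:
    """Emit planted edges in the STRING detailed-links dialect."""
    with Path(path).open("w") as handle:
        handle.write("protein1 protein2 experimental combined_score\n")
        for a, b, exp, comb in edges:
            handle.write(f"{a} {b} {exp} {comb}\n")


def emit_fixture(design: SimulationDesign, outdir: str | Path) -> GroundTruth:
    """Generate and write the complete fixture tree under ``outdir``:
    FASTA, one PSM TSV per band × condition × replicate, STRING-dialect
    evidence, MGF spectra with a spectrum→peptide assignment table, and
    ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome, truth = generate_proteome(design)
    write_fasta(proteome, outdir / "proteome.fasta")
    tables = generate_apms(design, proteome, truth)
    psm_dir = outdir / "psm"
    psm_dir.mkdir(exist_ok=True)
    for (band, condition, rep), records in sorted(tables.items()):
        write_psm_table(records, psm_dir / f"{band}_{condition}_r{rep}.tsv")
    write_evidence_file(truth.evidence_edges, outdir / "evidence.txt")
    spectra, assignments, truth = generate_phospho_spectra(design, proteome, truth)
    write_mgf(spectra, outdir / "spectra.mgf")
    write_assignments(assignments, outdir / "assignments.tsv")
    truth.to_json(outdir / "ground_truth.json")
    return truth
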