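"""A-score phosphosite localization and cross-replicate site accounting.

The localization score for a site placement is the difference of
-10·log10 cumulative-binomial probabilities of matched *site-determining*
ions between the two best-scoring phospho-isoforms of a peptide, evaluated
at the peak depth that maximizes their separation. Candidate spectra are
reduced per 100 m/z window to the d most intense peaks (d = 1..10) and
matched against singly protonated monoisotopic b/y ions; a phospho adds
+79.9663 Da to every ion whose span covers the site.

Peptides with a single candidate isoform are unambiguous: they receive a
capped sentinel score (1000) so downstream confidence banding (">19")
applies uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from apmsflow.errors import ParseError, ValidationError

# Monoisotopic residue masses (Da).
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
PROTON = 1.00727646688
WATER = 18.0105646863
PHOSPHO_DELTA = 79.9663

#: Per-depth weights for the weighted peptide score (depths 1..10).
DEPTH_WEIGHTS = (0.5, 0.75, 1.0, 1.0, 1.0, 1.0, 0.75, 0.5, 0.25, 0.25)
WINDOW_MZ = 100.0
#: Sentinel score for peptides with a single candidate isoform.
UNAMBIGUOUS_SENTINEL = 1000.0
MAX_DEPTH = 10


@dataclass
class FragmentSpectrum:
    """An MS2 spectrum: peaks sorted by m/z with positive intensities."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: np.ndarray  # shape (n, 2): mz, intensity

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks):
            if (self.peaks[:, 1] <= 0).any():
                raise ValidationError(f"spectrum {self.spectrum_id!r}: non-positive intensity")
            order = np.argsort(self.peaks[:, 0], kind="stable")
            self.peaks = self.peaks[order]


@dataclass(frozen=True)
class SiteIsoform:
    """One phospho placement of a peptide plus its theoretical b/y ladder."""

    peptide: str
    phospho_positions: frozenset[int]
    theoretical_ions: tuple[tuple[str, int, float], ...]

    def ion_mz(self) -> np.ndarray:
        return np.array([mz for _, _, mz in self.theoretical_ions])


@dataclass
class AscoreOutcome:
    spectrum_id: str
    best_isoform: SiteIsoform
    second_isoform: SiteIsoform | None
    peptide_scores: dict[frozenset[int], float]
    ascore_per_site: dict[int, float]
    optimal_depth: int
    #: for each best-isoform site, the competing placement position (or None)
    competitor_site: dict[int, int | None] = field(default_factory=dict)


@dataclass
class PhosphoSiteCall:
    """One aggregated protein-coordinate site (possibly a composite label)."""

    accession: str
    site_label: str
    coords: tuple[int, ...]
    n_detect_mid: int
    n_detect_high: int
    max_ascore: float


def theoretical_ions(peptide: str, phospho_positions: Iterable[int] = ()) -> SiteIsoform:
    """Singly protonated monoisotopic b/y ions of one phospho placement.

    Ions are generated for indices 1..len-1 in both series (2(n−1) ions);
    +79.9663 is added to each ion whose residue span covers a phosphosite.
    """
    positions = frozenset(phospho_positions)
    n = len(peptide)
    for pos in positions:
        if not 1 <= pos <= n:
            raise ValidationError(f"phospho position {pos} outside peptide of length {n}")
        if peptide[pos - 1] not in "STY":
            raise ValidationError(
                f"phospho position {pos} is {peptide[pos - 1]!r}, not S/T/Y"
            )
    try:
        masses = [RESIDUE_MASS[aa] for aa in peptide]
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r} in peptide {peptide!r}") from exc
    ions: list[tuple[str, int, float]] = []
    running = 0.0
    n_phospho_prefix = 0
    for i in range(1, n):
        running += masses[i - 1]
        if i in positions:
            n_phospho_prefix += 1
        ions.append(("b", i, running + PROTON + n_phospho_prefix * PHOSPHO_DELTA))
    running = 0.0
    n_phospho_suffix = 0
    for i in range(1, n):
        running += masses[n - i]
        if (n - i + 1) in positions:
            n_phospho_suffix += 1
        ions.append(("y", i, running + WATER + PROTON + n_phospho_suffix * PHOSPHO_DELTA))
    return SiteIsoform(peptide, positions, tuple(ions))


def reduce_to_depth(peaks: np.ndarray, depth: int) -> np.ndarray:
    """Keep the ``depth`` most intense peaks per contiguous 100 m/z window.

    Windows start at 0 ([0,100), [100,200), ...). Intensity ties break
    toward the lower m/z peak.
    """
    if not 1 <= depth <= MAX_DEPTH:
        raise ValidationError(f"depth must be in 1..{MAX_DEPTH}, got {depth}")
    peaks = np.asarray(peaks, dtype=float).reshape(-1, 2)
    if len(peaks) == 0:
        return peaks
    kept: list[np.ndarray] = []
    windows = np.floor(peaks[:, 0] / WINDOW_MZ).astype(int)
    for w in np.unique(windows):
        block = peaks[windows == w]
        order = np.lexsort((block[:, 0], -block[:, 1]))
        kept.append(block[order[:depth]])
    out = np.vstack(kept)
    return out[np.argsort(out[:, 0], kind="stable")]


def binomial_tail(n_trials: int, k_success: int, pi: float) -> float:
    """Upper-tail binomial probability P(X >= k) under Binomial(n, pi)."""
    if not 0 <= k_success <= n_trials:
        raise ValidationError(f"binomial_tail: need 0 <= k <= n, got k={k_success}, n={n_trials}")
    if not 0.0 < pi < 1.0:
        raise ValidationError(f"binomial_tail: pi must be in (0, 1), got {pi}")
    if k_success == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy computes it stably.
    return float(stats.binom.sf(k_success - 1, n_trials, pi))


def _count_matches(theo_mz: np.ndarray, peak_mz: np.ndarray, tolerance: float) -> int:
    """Number of theoretical ions with >=1 peak within ±tolerance."""
    if len(theo_mz) == 0 or len(peak_mz) == 0:
        return 0
    idx = np.searchsorted(peak_mz, theo_mz)
    left = np.clip(idx - 1, 0, len(peak_mz) - 1)
    right = np.clip(idx, 0, len(peak_mz) - 1)
    dist = np.minimum(np.abs(peak_mz[left] - theo_mz), np.abs(peak_mz[right] - theo_mz))
    return int((dist <= tolerance).sum())


def _depth_scores(
    reduced_by_depth: Sequence[np.ndarray],
    theo_mz: np.ndarray,
    tolerance: float,
) -> np.ndarray:
    """score_d = -10·log10 P(X >= k_d) with X ~ Binomial(n_ions, d/100)."""
    n = len(theo_mz)
    scores = np.zeros(MAX_DEPTH)
    if n == 0:
        return scores
    for d in range(1, MAX_DEPTH + 1):
        peaks = reduced_by_depth[d - 1]
        k = _count_matches(theo_mz, peaks[:, 0] if len(peaks) else np.empty(0), tolerance)
        tail = binomial_tail(n, k, d / 100.0)
        scores[d - 1] = -10.0 * math.log10(tail) if tail > 0 else math.inf
    return scores


def peptide_score(
    spectrum: FragmentSpectrum,
    isoform: SiteIsoform,
    tolerance: float = 0.05,
    weights: Sequence[float] = DEPTH_WEIGHTS,
) -> tuple[np.ndarray, float]:
    """Per-depth and weighted binomial scores of one isoform vs a spectrum.

    For each depth d = 1..10 the spectrum is reduced to its d most intense
    peaks per 100 m/z window; k = matched theoretical ions within
    ±tolerance, n = total theoretical ions, and score_d =
    -10·log10 P(X >= k | Binomial(n, d/100)). The weighted score averages
    the depth scores with the configured weights. An empty spectrum scores
    0 at every depth.
    """
    if tolerance <= 0:
        raise ValidationError(f"tolerance must be positive, got {tolerance}")
    reduced = [reduce_to_depth(spectrum.peaks, d) for d in range(1, MAX_DEPTH + 1)]
    scores = _depth_scores(reduced, isoform.ion_mz(), tolerance)
    weights = np.asarray(weights, dtype=float)
    weighted = float((weights * scores).sum() / weights.sum())
    return scores, weighted


def _site_determining(a: SiteIsoform, b: SiteIsoform) -> tuple[np.ndarray, np.ndarray]:
    """m/z arrays of ions unique to a and to b (rounded-4 set difference)."""
    mz_a = {round(mz, 4) for _, _, mz in a.theoretical_ions}
    mz_b = {round(mz, 4) for _, _, mz in b.theoretical_ions}
    only_a = np.array(sorted(m for _, _, m in a.theoretical_ions if round(m, 4) not in mz_b))
    only_b = np.array(sorted(m for _, _, m in b.theoretical_ions if round(m, 4) not in mz_a))
    return only_a, only_b


def _separation(
    reduced: Sequence[np.ndarray],
    best: SiteIsoform,
    other: SiteIsoform,
    tolerance: float,
) -> tuple[float, int]:
    """Max over depths of score(best, SD ions) − score(other, SD ions)."""
    sd_best, sd_other = _site_determining(best, other)
    s_best = _depth_scores(reduced, sd_best, tolerance)
    s_other = _depth_scores(reduced, sd_other, tolerance)
    sep = s_best - s_other
    depth = int(np.argmax(sep)) + 1  # argmax takes the first (lowest) depth on ties
    return float(max(0.0, sep[depth - 1])), depth


def ascore(
    spectrum: FragmentSpectrum,
    peptide: str,
    n_phospho: int = 1,
    tolerance: float = 0.05,
    weights: Sequence[float] = DEPTH_WEIGHTS,
) -> AscoreOutcome:
    """Localize ``n_phospho`` phosphosites on ``peptide`` from one spectrum.

    All site isoforms are enumerated and ranked by weighted peptide score
    (ties break toward the lexicographically smallest position set, so the
    result is deterministic). The headline score contrasts the top two
    isoforms on their site-determining ions at the depth maximizing the
    separation; per-site scores contrast the best isoform with its best
    competitor lacking that site.
    """
    candidates = [i + 1 for i, aa in enumerate(peptide) if aa in "STY"]
    if n_phospho > len(candidates):
        raise ValidationError(
            f"peptide {peptide!r} has {len(candidates)} S/T/Y site(s), "
            f"cannot place {n_phospho} phospho group(s)"
        )
    isoforms = [
        theoretical_ions(peptide, combo) for combo in combinations(candidates, n_phospho)
    ]
    scored: list[tuple[float, SiteIsoform]] = []
    for iso in isoforms:
        _, weighted = peptide_score(spectrum, iso, tolerance, weights)
        scored.append((weighted, iso))
    scored.sort(key=lambda sw: (-sw[0], tuple(sorted(sw[1].phospho_positions))))
    peptide_scores = {iso.phospho_positions: w for w, iso in scored}
    best = scored[0][1]

    if len(scored) == 1:
        return AscoreOutcome(
            spectrum_id=spectrum.spectrum_id,
            best_isoform=best,
            second_isoform=None,
            peptide_scores=peptide_scores,
            ascore_per_site={pos: UNAMBIGUOUS_SENTINEL for pos in best.phospho_positions},
            optimal_depth=1,
            competitor_site={pos: None for pos in best.phospho_positions},
        )

    reduced = [reduce_to_depth(spectrum.peaks, d) for d in range(1, MAX_DEPTH + 1)]
    second = scored[1][1]
    _, optimal_depth = _separation(reduced, best, second, tolerance)

    ascore_per_site: dict[int, float] = {}
    competitor_site: dict[int, int | None] = {}
    for pos in sorted(best.phospho_positions):
        competitor = next(
            (iso for _, iso in scored if pos not in iso.phospho_positions), None
        )
        if competitor is None:
            ascore_per_site[pos] = UNAMBIGUOUS_SENTINEL
            competitor_site[pos] = None
            continue
        a, _ = _separation(reduced, best, competitor, tolerance)
        ascore_per_site[pos] = a
        moved = sorted(competitor.phospho_positions - best.phospho_positions)
        competitor_site[pos] = moved[0] if moved else None
    return AscoreOutcome(
        spectrum_id=spectrum.spectrum_id,
        best_isoform=best,
        second_isoform=second,
        peptide_scores=peptide_scores,
        ascore_per_site=ascore_per_site,
        optimal_depth=optimal_depth,
        competitor_site=competitor_site,
    )


def confidence_from_ascore(a: float) -> float:
    """Percent confidence implied by a localization score:
    100 × (1 − 10^(−A/10)). A=15 → ≈96.84 (>90% band); A=20 → 99.0."""
    if a < 0:
        raise ValidationError(f"A-score must be non-negative, got {a}")
    return 100.0 * (1.0 - 10.0 ** (-a / 10.0))


# ---------------------------------------------------------------------------
# cross-replicate aggregation


@dataclass(frozen=True)
class SiteEvidence:
    """One replicate-level localization at protein coordinates.

    ``coords`` holds the (already offset-adjusted) coordinate of the
    assigned site, plus the adjacent competing coordinate when the
    localization was ambiguous (A below the ambiguity threshold).
    """

    accession: str
    coords: tuple[int, ...]
    residues: tuple[str, ...]
    ascore: float
    replicate: int


def merge_site_evidence(
    evidence: Sequence[SiteEvidence],
    mid_band: tuple[float, float] = (15.0, 19.0),
) -> list[PhosphoSiteCall]:
    """Merge replicate-level site evidence into labelled site calls.

    Coordinates linked by any ambiguous observation (multi-coordinate
    evidence) are unioned into a composite site; labels follow the
    "S25/26" convention (residue letter of each coordinate, letter shown
    once when shared). Detection counts use ``mid_band`` inclusive for the
    middle confidence band and strictly above its upper edge for the high
    band.
    """
    lo, hi = mid_band
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x: tuple[str, int]) -> tuple[str, int]:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: tuple[str, int], b: tuple[str, int]) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    residue_letter: dict[tuple[str, int], str] = {}
    for ev in evidence:
        keys = [(ev.accession, c) for c in ev.coords]
        for key, letter in zip(keys, ev.residues):
            find(key)
            residue_letter.setdefault(key, letter)
        for other in keys[1:]:
            union(keys[0], other)

    groups: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for key in parent:
        groups.setdefault(find(key), []).append(key)

    calls: list[PhosphoSiteCall] = []
    for root, members in groups.items():
        members.sort()
        accession = root[0]
        coords = tuple(c for _, c in members)
        letters = [residue_letter[m] for m in members]
        if len(set(letters)) == 1:
            label = letters[0] + "/".join(str(c) for c in coords)
        else:
            label = "/".join(f"{l}{c}" for l, c in zip(letters, coords))
        n_mid = n_high = 0
        max_a = 0.0
        for ev in evidence:
            if ev.accession != accession:
                continue
            if find((ev.accession, ev.coords[0])) != root:
                continue
            if lo <= ev.ascore <= hi:
                n_mid += 1
            elif ev.ascore > hi:
                n_high += 1
            max_a = max(max_a, ev.ascore)
        calls.append(PhosphoSiteCall(accession, label, coords, n_mid, n_high, max_a))
    calls.sort(key=lambda c: (c.accession, c.coords[0]))
    return calls


def aggregate_sites(
    outcomes: Sequence[tuple[AscoreOutcome, int]],
    peptide_locations: Mapping[str, tuple[str, int]],
    mature_offset: int = 0,
    ambiguity_threshold: float = 15.0,
    mid_band: tuple[float, float] = (15.0, 19.0),
) -> list[PhosphoSiteCall]:
    """Convert replicate A-score outcomes to protein-coordinate site calls.

    ``outcomes`` pairs each :class:`AscoreOutcome` with its replicate
    number; ``peptide_locations`` maps each peptide to its (accession,
    1-based start) placement in the protein. Coordinates are shifted by
    ``mature_offset`` (signal-peptide length). A site whose score against
    an *adjacent* competing residue falls below ``ambiguity_threshold`` is
    linked to that residue, and linked coordinates merge into composite
    labels. Detections are counted per PSM.
    """
    evidence: list[SiteEvidence] = []
    for outcome, replicate in outcomes:
        peptide = outcome.best_isoform.peptide
        if peptide not in peptide_locations:
            raise ValidationError(f"peptide {peptide!r} has no protein placement")
        accession, start = peptide_locations[peptide]
        for pos in sorted(outcome.best_isoform.phospho_positions):
            a = outcome.ascore_per_site[pos]
            coord = start + pos - 1 - mature_offset
            coords = [coord]
            residues = [peptide[pos - 1]]
            competitor = outcome.competitor_site.get(pos)
            if (
                competitor is not None
                and a < ambiguity_threshold
                and abs(competitor - pos) == 1
            ):
                coords.append(start + competitor - 1 - mature_offset)
                residues.append(peptide[competitor - 1])
            evidence.append(
                SiteEvidence(accession, tuple(coords), tuple(residues), a, replicate)
            )
    return merge_site_evidence(evidence, mid_band)


def write_site_table(calls: Sequence[PhosphoSiteCall], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("accession\tsite\tmax_ascore\tn_detect_15_19\tn_detect_gt19\n")
        for call in calls:
            handle.write(
                f"{call.accession}\t{call.site_label}\t{call.max_ascore:.4g}\t"
                f"{call.n_detect_mid}\t{call.n_detect_high}\n"
            )


# ---------------------------------------------------------------------------
# MGF input/output (deliberately minimal: BEGIN IONS blocks with
# TITLE/PEPMASS/CHARGE and "mz intensity" peak lines)


def read_mgf(path: str | Path) -> list[FragmentSpectrum]:
    spectra: list[FragmentSpectrum] = []
    title = ""
    pepmass = 0.0
    charge = 0
    peaks: list[tuple[float, float]] = []
    in_block = False
    with Path(path).open() as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block = True
                title, pepmass, charge, peaks = "", 0.0, 0, []
            elif line == "END IONS":
                if not in_block:
                    raise ParseError(f"{path}: line {line_no}: END IONS without BEGIN IONS")
                spectra.append(FragmentSpectrum(title, pepmass, charge, np.array(peaks).reshape(-1, 2)))
                in_block = False
            elif not in_block:
                continue
            elif line.startswith("TITLE="):
                title = line[len("TITLE="):]
            elif line.startswith("PEPMASS="):
                pepmass = float(line[len("PEPMASS="):].split()[0])
            elif line.startswith("CHARGE="):
                charge = int(line[len("CHARGE="):].rstrip("+-"))
            elif "=" in line:
                continue
            else:
                try:
                    mz_s, int_s = line.split()[:2]
                    peaks.append((float(mz_s), float(int_s)))
                except ValueError as exc:
                    raise ParseError(f"{path}: line {line_no}: malformed peak line {line!r}") from exc
    if in_block:
        raise ParseError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spectrum.spectrum_id}\n")
            handle.write(f"PEPMASS={spectrum.precursor_mz:.5f}\n")
            handle.write(f"CHARGE={spectrum.charge}+\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz:.5f} {intensity:.2f}\n")
            handle.write("END IONS\n")
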