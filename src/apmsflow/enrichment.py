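"""Bait-vs-control enrichment testing and replicate/overlap accounting.

Missing detections are zero-filled before testing: absence from a control
run is evidence of enrichment, and the quantification matrix records every
protein in every sample. Significance requires both p < alpha and
mean_bait > mean_control (two-sided Welch test plus a direction rule, the
conservative reading of "enriched"). The all-replicates consistency flag is
tracked separately so callers can apply the detected-in-every-bait-repeat
filter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from apmsflow.errors import DegenerateInputError, ValidationError
from apmsflow.quantify import QuantMatrix


@dataclass
class EnrichmentResult:
    accession: str
    band: str
    mean_bait: float
    mean_control: float
    t_stat: float
    df: float
    p_value: float
    n_bait_detected: int
    significant: bool
    consistent: bool
    degenerate: bool = False


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns ``(t, df, p)``.

    t = (x̄−ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ) with Welch–Satterthwaite degrees of
    freedom and a two-sided p-value. Raises :class:`DegenerateInputError`
    when both sample variances are zero; the caller decides how to handle
    that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t: each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise DegenerateInputError("welch_t: both sample variances are zero")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    n = len(pvalues)
    order = np.argsort(pvalues)
    ranked = pvalues[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich_band(
    quant: QuantMatrix,
    band: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Per-protein Welch test of bait vs control SI_GI within one band.

    Zero-filled vectors come straight from the QuantMatrix. Degenerate
    (both-variances-zero) proteins get p=1 when the means are identical and
    p=0 (flagged) otherwise. Results are sorted by descending mean_bait.
    """
    if band not in quant.bands():
        raise ValidationError(f"band {band!r} not present in matrix (has {quant.bands()})")
    bait_cols = [quant.samples.index(s) for s in quant.band_samples(band, "bait")]
    ctrl_cols = [quant.samples.index(s) for s in quant.band_samples(band, "control")]
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError(f"band {band!r}: need >=2 bait and >=2 control samples")

    raw: list[EnrichmentResult] = []
    for i, acc in enumerate(quant.proteins):
        x = quant.values[i, bait_cols]
        y = quant.values[i, ctrl_cols]
        mean_bait = float(x.mean())
        mean_control = float(y.mean())
        degenerate = False
        try:
            t, df, p = welch_t(x, y)
        except DegenerateInputError:
            degenerate = True
            t, df = 0.0, float(len(x) + len(y) - 2)
            p = 1.0 if mean_bait == mean_control else 0.0
        raw.append(
            EnrichmentResult(
                accession=acc,
                band=band,
                mean_bait=mean_bait,
                mean_control=mean_control,
                t_stat=t,
                df=df,
                p_value=p,
                n_bait_detected=int((x > 0).sum()),
                significant=False,
                consistent=bool((x > 0).all()),
                degenerate=degenerate,
            )
        )

    pvals = np.array([r.p_value for r in raw])
    effective = _bh_adjust(pvals) if bh_correct else pvals
    for r, p_eff in zip(raw, effective):
        r.significant = bool(p_eff < alpha and r.mean_bait > r.mean_control)
    raw.sort(key=lambda r: -r.mean_bait)
    return raw


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    cols = (
        "accession\tband\tmean_bait\tmean_control\tt_stat\tdf\tp_value\t"
        "n_bait_detected\tsignificant\tconsistent\tdegenerate\n"
    )
    with open(path, "w") as handle:
        handle.write(cols)
        for r in results:
            handle.write(
                f"{r.accession}\t{r.band}\t{r.mean_bait:.6g}\t{r.mean_control:.6g}\t"
                f"{r.t_stat:.6g}\t{r.df:.6g}\t{r.p_value:.6g}\t{r.n_bait_detected}\t"
                f"{int(r.significant)}\t{int(r.consistent)}\t{int(r.degenerate)}\n"
            )


def overlap_counts(sets: Mapping[str, set]) -> dict[str, int]:
    """Venn-region counts for 2–4 named sets.

    Every region (each non-empty combination of set names, joined by "∩")
    is reported with the count of elements belonging to exactly those sets;
    region counts sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValidationError(f"overlap_counts supports 2-4 sets, got {len(names)}")
    counts: dict[str, int] = {}
    membership: dict[object, frozenset[str]] = {}
    for name in names:
        for element in sets[name]:
            membership[element] = membership.get(element, frozenset()) | {name}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = "∩".join(combo)
            counts[key] = sum(1 for m in membership.values() if m == frozenset(combo))
    return counts
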