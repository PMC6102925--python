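"""Synthetic long-read generator over a repeat locus.

Reads are built as flank_up + motif*units + flank_down, then distorted
by a per-base error model, per-repeat-unit truncation, strand flips and
short-fragment loading bias — the statistical structure the analysis
stages assume:

* allele mosaicism: unit counts drawn from a mixture of point masses
  and/or normal components;
* platform error profiles: indel-dominated (PacBio-like) or high-error
  with systematic G/C->A miscalls (ONT-like);
* truncation: a geometric per-repeat-unit hazard, so the chance of
  reading through u units is (1-h)^u — the simplest mechanism consistent
  with a polymerase less likely to traverse longer repeats;
* loading bias: allele draws reweighted by (fragment length)^-beta,
  over-representing short fragments.

Identical config (including seed) yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LongRead, RepeatLocus, reverse_complement, write_sequences

__all__ = [
    "ErrorModel",
    "SimConfig",
    "TruthRecord",
    "PACBIO_RS2_ERRORS",
    "ONT_MINION_ERRORS",
    "PACBIO_RS2_HAZARD",
    "ONT_MINION_HAZARD",
    "default_locus",
    "noamp_config",
    "draw_alleles",
    "emit_read",
    "simulate_reads",
    "simulate_dataset",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error probabilities applied to the true read sequence.

    ``gc_to_a_bias`` is an extra, systematic probability that a G or C is
    miscalled as A (applied before the generic substitution draw).
    """

    p_mismatch: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0
    gc_to_a_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_mismatch", "p_ins", "p_del", "gc_to_a_bias"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1): got {p}")


# Platform presets. Generative rates are calibrated so the *measured*
# median NW error rate over an expanded repeat reproduces the platform
# medians (7.4% PacBio RS II, 47.3% ONT MinION); truncation hazards solve
# (1-h)^774 for the platform read-through fractions (0.438 and 0.835).
PACBIO_RS2_ERRORS = ErrorModel(p_mismatch=0.014, p_ins=0.04, p_del=0.02)
ONT_MINION_ERRORS = ErrorModel(p_mismatch=0.02, p_ins=0.05, p_del=0.05, gc_to_a_bias=0.42)
PACBIO_RS2_HAZARD = 1.0 - 0.438 ** (1.0 / 774.0)
ONT_MINION_HAZARD = 1.0 - 0.835 ** (1.0 / 774.0)

# Allele spec: an int (fixed unit count) or ("normal", mean, sd).
AlleleSpec = int | tuple


@dataclass(frozen=True)
class SimConfig:
    locus: RepeatLocus
    alleles: tuple[tuple[AlleleSpec, float], ...]
    n_reads: int
    error_model: ErrorModel = ErrorModel()
    truncation_hazard: float = 0.0
    loading_bias: float = 0.0  # exponent beta in weight ~ length^-beta
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("allele list must be non-empty")
        object.__setattr__(self, "alleles", tuple((a, float(w)) for a, w in self.alleles))
        total = sum(w for _, w in self.alleles)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele weights must sum to 1 (got {total})")
        if not 0.0 <= self.truncation_hazard < 1.0:
            raise ValueError("truncation_hazard must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass
class TruthRecord:
    read_id: str
    true_units: int
    true_repeat_nt: int
    allele_index: int
    truncated: bool
    strand: str
    emitted_units: int = 0


def default_locus(
    motif: str = "GGGGCC",
    flank_len: int = 100,
    reference_units: int = 3,
    seed: int = 20180821,
) -> RepeatLocus:
    """A synthetic repeat locus with random (motif-free) flanks.

    The flanks are synthetic stand-ins for the reference sequence
    adjacent to a repeat locus; the reference repeat span defaults to
    three motif copies (the hg38 C9orf72 configuration).
    """
    rng = np.random.default_rng(seed)
    tandem = motif * 2

    def _flank() -> str:
        while True:
            seq = "".join(rng.choice(list(_BASES), size=flank_len))
            if tandem not in seq and tandem not in reverse_complement(seq):
                return seq

    start = 1000
    return RepeatLocus(
        name="synthetic-repeat-locus",
        reference_name="ref_synthetic",
        repeat_start=start,
        repeat_end=start + reference_units * len(motif),
        motif=motif,
        flank_up=_flank(),
        flank_down=_flank(),
    )


def noamp_config(n_reads: int = 828, seed: int = 0, locus: RepeatLocus | None = None) -> SimConfig:
    """Targeted-enrichment preset: 2-unit wild type plus a mosaic expansion.

    Underlying allele mass is concentrated near 870 units with a smaller
    ~110-unit population; after the loading-bias law (beta=1) and the
    per-unit truncation hazard, the *spanning* read mix is ~84% wild
    type / ~16% expanded with both expansion modes represented,
    mirroring what targeted long-read data over such a locus looks like.
    """
    return SimConfig(
        locus=locus if locus is not None else default_locus(),
        alleles=((2, 0.13), (("normal", 110.0, 15.0), 0.06), (("normal", 870.0, 80.0), 0.81)),
        n_reads=n_reads,
        error_model=PACBIO_RS2_ERRORS,
        truncation_hazard=PACBIO_RS2_HAZARD,
        loading_bias=1.0,
        seed=seed,
    )


def _sample_spec(spec: AlleleSpec, rng: np.random.Generator) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind = spec[0]
    if kind == "normal":
        _, mean, sd = spec
        return max(1, int(round(rng.normal(mean, sd))))
    raise ValueError(f"unknown allele spec {spec!r}")


def draw_alleles(config: SimConfig, rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Draw ``n_reads`` (unit count, allele index) pairs from the mixture.

    Loading bias is applied by rejection sampling with acceptance
    probability (L_min / L)^beta, where L = flanks + repeat length, so
    the realized draw law is weight * L^-beta up to normalization.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = np.array([w for _, w in config.alleles])
    weights = weights / weights.sum()
    flanks = len(config.locus.flank_up) + len(config.locus.flank_down)
    m = config.locus.motif_len
    l_min = flanks + m  # shortest conceivable fragment (one unit)
    beta = config.loading_bias
    out: list[tuple[int, int]] = []
    while len(out) < config.n_reads:
        idx = int(rng.choice(len(weights), p=weights))
        units = _sample_spec(config.alleles[idx][0], rng)
        if beta > 0.0:
            accept = (l_min / (flanks + units * m)) ** beta
            if rng.random() >= accept:
                continue
        out.append((units, idx))
    return out


def _apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    out: list[str] = []
    for base in seq:
        if model.p_del > 0 and rng.random() < model.p_del:
            pass  # deletion
        else:
            emitted = base
            if base in "GC" and model.gc_to_a_bias > 0 and rng.random() < model.gc_to_a_bias:
                emitted = "A"
            elif model.p_mismatch > 0 and rng.random() < model.p_mismatch:
                emitted = _BASES[(_BASES.index(base) + rng.integers(1, 4)) % 4]
            out.append(emitted)
        if model.p_ins > 0 and rng.random() < model.p_ins:
            out.append(_BASES[rng.integers(0, 4)])
    return "".join(out)


def emit_read(
    true_units: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    read_id: str = "sim_read",
    allele_index: int = 0,
) -> tuple[LongRead, TruthRecord]:
    """Emit one read for an allele of ``true_units`` motif copies.

    Truncation applies a geometric per-unit hazard: a read that fails
    during unit k carries k-1 complete units and no downstream flank.
    Errors are applied afterwards; the strand is flipped with
    probability one half.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    locus = config.locus
    h = config.truncation_hazard
    if h > 0.0:
        first_failure = int(rng.geometric(h))  # 1-based unit of failure
        truncated = first_failure <= true_units
        emitted_units = first_failure - 1 if truncated else true_units
    else:
        truncated = False
        emitted_units = true_units
    truth_seq = locus.flank_up + locus.motif * emitted_units
    if not truncated:
        truth_seq += locus.flank_down
    seq = _apply_errors(truth_seq, config.error_model, rng)
    strand = "forward" if rng.random() < 0.5 else "reverse"
    if strand == "reverse":
        seq = reverse_complement(seq)
    if not seq:  # pathological: everything deleted
        seq = "N"
    read = LongRead(read_id, seq, qualities=[30] * len(seq))
    truth = TruthRecord(
        read_id=read_id,
        true_units=true_units,
        true_repeat_nt=true_units * locus.motif_len,
        allele_index=allele_index,
        truncated=truncated,
        strand=strand,
        emitted_units=emitted_units,
    )
    return read, truth


def simulate_reads(config: SimConfig) -> tuple[list[LongRead], list[TruthRecord]]:
    """Generate the full read set plus ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    draws = draw_alleles(config, rng)
    reads: list[LongRead] = []
    truths: list[TruthRecord] = []
    for i, (units, idx) in enumerate(draws):
        read, truth = emit_read(units, config, rng, read_id=f"sim_{i:06d}", allele_index=idx)
        reads.append(read)
        truths.append(truth)
    return reads, truths


def truth_table(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "true_units": [t.true_units for t in truths],
            "true_repeat_nt": [t.true_repeat_nt for t in truths],
            "allele_index": [t.allele_index for t in truths],
            "truncated": [t.truncated for t in truths],
            "strand": [t.strand for t in truths],
            "emitted_units": [t.emitted_units for t in truths],
        }
    )


def simulate_dataset(
    config: SimConfig,
    out_reads: str | Path,
    out_truth: str | Path,
) -> dict:
    """Write FASTQ + truth TSV; return a run summary.

    The summary records per-allele read counts and realized spanning
    (read-through) fractions.
    """
    reads, truths = simulate_reads(config)
    try:
        write_sequences(reads, out_reads, format="fastq")
    except OSError as exc:
        raise OSError(f"cannot write reads to {out_reads}: {exc}") from exc
    table = truth_table(truths)
    try:
        table.to_csv(out_truth, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write truth table to {out_truth}: {exc}") from exc
    summary: dict = {"n_reads": len(reads), "alleles": []}
    for idx, (spec, weight) in enumerate(config.alleles):
        sub = table[table.allele_index == idx]
        summary["alleles"].append(
            {
                "index": idx,
                "spec": repr(spec),
                "weight": weight,
                "n_reads": int(len(sub)),
                "spanning_fraction": float((~sub.truncated).mean()) if len(sub) else float("nan"),
            }
        )
    return summary
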