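"""SNP genotyping assay designability filters.

A candidate SNP is considered designable when its flanking-sequence
context passes four rules: local GC content below a threshold (default
0.65), no indel within 30 bp of the target variant, no additional variant
within 20 bp, and flanking primer seeds that map to a single location in
the reference.  Distance windows are inclusive ("within N bp" means
distance <= N).  Primer uniqueness is approximated by exact k-mer lookup
of the two flanking seeds on both strands, which is deterministic and
needs no aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import AssayContext

log = logging.getLogger(__name__)

RULES = ("gc", "indel30", "snp20", "multimap")

#: Default rule thresholds.
DEFAULT_RULES = {"gc_max": 0.65, "indel_window": 30, "snp_window": 20, "uniq_k": 20, "gc_flank": 50}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DesignVerdict:
    """Outcome of the designability rules for one candidate locus."""

    locus_id: str
    designable: bool
    failed_rules: list[str] = field(default_factory=list)
    gc_fraction: float = float("nan")
    multimap_status: str = "not_evaluated"  # unique | multimap | not_evaluated

    def __post_init__(self) -> None:
        assert self.designable == (len(self.failed_rules) == 0)


def gc_fraction(seq: str, window: tuple[int, int] | None = None) -> float:
    """G+C fraction of ``seq[lo:hi]``, case-insensitive, N bases excluded.

    Returns NaN when the effective window is empty (all-N), which callers
    treat as a conservative rule failure.
    """
    lo, hi = window if window is not None else (0, len(seq))
    if not (0 <= lo < hi <= len(seq)):
        raise ValueError(f"window ({lo}, {hi}) outside sequence of length {len(seq)}")
    sub = seq[lo:hi].upper()
    counted = sum(1 for b in sub if b in "ACGT")
    if counted == 0:
        return float("nan")
    gc = sum(1 for b in sub if b in "GC")
    return gc / counted


def check_unique_mapping(ctx: AssayContext, reference: dict[str, str], k: int) -> str:
    """Exact-lookup uniqueness of the two k-base primer seeds flanking the target.

    Each seed (the k bases immediately left and right of the target base)
    is counted across the reference sequences on both strands; more than
    one hit for either seed means ``"multimap"``.  A flank shorter than k
    cannot be evaluated.
    """
    lo, hi = ctx.target_offset, ctx.target_offset + 1
    left = ctx.flank_seq[lo - k : lo].upper()
    right = ctx.flank_seq[hi : hi + k].upper()
    if len(left) < k or len(right) < k:
        log.warning("%s: flank shorter than k=%d; uniqueness not evaluated", ctx.locus_id, k)
        return "not_evaluated"
    for seed in (left, right):
        hits = 0
        rc = reverse_complement(seed)
        for seq in reference.values():
            s = seq.upper()
            hits += s.count(seed) + (s.count(rc) if rc != seed else 0)
            if hits > 1:
                return "multimap"
        if hits > 1:  # pragma: no cover - returned above
            return "multimap"
    return "unique"


def check_designable(
    ctx: AssayContext,
    rules: dict | None = None,
    reference: dict[str, str] | None = None,
) -> DesignVerdict:
    """Apply all designability rules to one context.

    GC is evaluated over a symmetric window of ``gc_flank`` bases each
    side of the target (clipped to the sequence).  The multimap rule is
    evaluated only when a reference is supplied; otherwise it is reported
    as not evaluated and does not fail the assay.
    """
    r = {**DEFAULT_RULES, **(rules or {})}
    failed: list[str] = []

    lo = max(0, ctx.target_offset - r["gc_flank"])
    hi = min(len(ctx.flank_seq), ctx.target_offset + r["gc_flank"] + 1)
    gc = gc_fraction(ctx.flank_seq, (lo, hi))
    if not (gc < r["gc_max"]):  # NaN (all-N window) fails conservatively
        failed.append("gc")

    for off, kind in ctx.nearby_variants:
        dist = abs(off - ctx.target_offset)
        if kind == "indel" and dist <= r["indel_window"] and "indel30" not in failed:
            failed.append("indel30")
        if kind == "snp" and dist <= r["snp_window"] and "snp20" not in failed:
            failed.append("snp20")

    mm = "not_evaluated"
    if reference is not None:
        mm = check_unique_mapping(ctx, reference, r["uniq_k"])
        if mm == "multimap":
            failed.append("multimap")

    order = {name: i for i, name in enumerate(RULES)}
    failed.sort(key=order.__getitem__)
    return DesignVerdict(ctx.locus_id, not failed, failed, gc, mm)


def filter_assays(
    contexts: list[AssayContext],
    rules: dict | None = None,
    reference: dict[str, str] | None = None,
):
    """Run the designability rules over a batch of contexts.

    Returns (verdicts, summary) where summary counts failures per rule
    plus the number of designable contexts.  A context failing several
    rules appears once in the designable tally but in every rule tally it
    fails.
    """
    verdicts = [check_designable(ctx, rules, reference) for ctx in contexts]
    summary = {rule: sum(rule in v.failed_rules for v in verdicts) for rule in RULES}
    summary["n_total"] = len(verdicts)
    summary["n_designable"] = sum(v.designable for v in verdicts)
    return verdicts, summary


def verdicts_frame(verdicts: list[DesignVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [v.locus_id for v in verdicts],
            "designable": [v.designable for v in verdicts],
            "failed_rules": [",".join(v.failed_rules) for v in verdicts],
            "gc_fraction": [v.gc_fraction for v in verdicts],
            "multimap_status": [v.multimap_status for v in verdicts],
        }
    )
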