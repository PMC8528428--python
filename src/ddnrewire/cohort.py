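"""Dichotomize per-compound dose-response summaries into sensitive/resistant cohorts.

For one compound, samples in the lower ``lower_q`` tail of the AUC
distribution (strongest kill) are drug-sensitive, those in the upper
``upper_q`` tail are drug-resistant, and the middle is excluded.  The
default tertile split (lower_q = upper_q = 1/3) gives balanced groups.
Underpowered or tie-degenerate compounds are flagged, not fatal, so a
(drug, cluster) analysis can be skipped rather than aborting a run.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import DrugResponseTable

#: skip reasons a partition can carry
UNDERPOWERED = "underpowered"
DEGENERATE_TIES = "degenerate_ties"


@dataclass(frozen=True)
class ConditionPartition:
    """Sample -> {sensitive, resistant, excluded} assignment for one compound.

    ``quantile_bounds`` records the (lower_q, upper_q) tail fractions used.
    When ``skip_reason`` is set the partition must not be analyzed.
    """

    compound_id: str
    sensitive_ids: frozenset
    resistant_ids: frozenset
    excluded_ids: frozenset
    quantile_bounds: tuple[float, float]
    skip_reason: str | None = None

    def __post_init__(self) -> None:
        if self.sensitive_ids & self.resistant_ids:
            raise ValidationError("sensitive and resistant sets overlap")

    @property
    def n_sensitive(self) -> int:
        return len(self.sensitive_ids)

    @property
    def n_resistant(self) -> int:
        return len(self.resistant_ids)

    def write_tsv(self, path: str | Path) -> Path:
        """Two-column (sample, label) export, sorted by sample id."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        labels = {s: "sensitive" for s in self.sensitive_ids}
        labels.update({s: "resistant" for s in self.resistant_ids})
        labels.update({s: "excluded" for s in self.excluded_ids})
        with open(path, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for s in sorted(labels):
                fh.write(f"{s}\t{labels[s]}\n")
        return path


def partition_by_response(
    table: DrugResponseTable,
    compound_id: str,
    lower_q: float = 1 / 3,
    upper_q: float = 1 / 3,
    min_group_size: int = 15,
) -> ConditionPartition:
    """Split the samples with a response record for ``compound_id`` into cohorts.

    Thresholds are empirical type-7 (linearly interpolated) quantiles:
    sensitive means ``auc <= Q(lower_q)``, resistant ``auc >= Q(1 - upper_q)``
    (lower area under the dose-response curve = stronger kill).  Ties at a
    boundary all go to the extreme group.  Samples that would qualify for
    both groups (possible only under heavy ties) are excluded and the
    partition is flagged ``degenerate_ties``; groups smaller than
    ``min_group_size`` flag ``underpowered``.
    """
    if not (0.0 < lower_q < 1.0 and 0.0 < upper_q < 1.0):
        raise ValidationError("quantile bounds must lie in (0, 1)")
    if lower_q + upper_q > 1.0 + 1e-12:
        raise ValidationError("lower_q + upper_q must not exceed 1")
    recs = table.for_compound(compound_id)
    if not recs:
        raise ValidationError(f"compound {compound_id!r} absent from response table")
    # sort by sample id so the result is invariant to record order
    recs = sorted(recs, key=lambda r: r.sample_id)
    samples = np.array([r.sample_id for r in recs])
    aucs = np.array([r.auc for r in recs], dtype=float)

    lo = float(np.quantile(aucs, lower_q))
    hi = float(np.quantile(aucs, 1.0 - upper_q))
    sens = aucs <= lo
    res = aucs >= hi
    both = sens & res
    reason = None
    if both.any():
        sens &= ~both
        res &= ~both
        reason = DEGENERATE_TIES
    excluded = ~(sens | res)
    if reason is None and (sens.sum() < min_group_size or res.sum() < min_group_size):
        reason = UNDERPOWERED
    return ConditionPartition(
        compound_id=compound_id,
        sensitive_ids=frozenset(samples[sens]),
        resistant_ids=frozenset(samples[res]),
        excluded_ids=frozenset(samples[excluded]),
        quantile_bounds=(lower_q, upper_q),
        skip_reason=reason,
    )
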