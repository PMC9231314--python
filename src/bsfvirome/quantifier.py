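"""TPM quantification over CDS features and housekeeping-gene ratios.

TPM (transcripts per million) length-normalises read counts and rescales so
every sample sums to 10^6: ``rate_i = count_i / length_i`` and
``TPM_i = 1e6 * rate_i / sum(rates)``. The denominator uses only the
supplied feature set, so comparisons are within that set. Viral RNA load is
expressed as the ratio of a viral CDS's TPM to that of a constitutively
expressed housekeeping gene (e.g. Actin-5C), rounded half-even.

Read filtering is abstracted to "one placement per read": a multi-placed
read counts toward its single best placement, with ties dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CdsFeature",
    "TpmTable",
    "count_reads",
    "read_sam_placements",
    "tpm",
    "tpm_table",
    "expression_ratio",
    "ratio_report",
]


@dataclass
class CdsFeature:
    """A CDS feature with per-sample read counts."""

    feature_id: str
    length_nt: int
    sample_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")
        for sample, count in self.sample_counts.items():
            if count < 0:
                raise ValueError(f"negative count for {self.feature_id}/{sample}")


@dataclass(frozen=True)
class TpmTable:
    """Per-sample TPM values and housekeeping ratios."""

    samples: tuple[str, ...]
    values: dict[tuple[str, str], float]  # (feature, sample) -> TPM
    ratios: dict[tuple[str, str, str], float]  # (feature, housekeeping, sample)

    def frame(self) -> pd.DataFrame:
        features = sorted({f for f, _ in self.values})
        return pd.DataFrame(
            {s: [self.values[(f, s)] for f in features] for s in self.samples},
            index=features,
        )


def count_reads(
    placements: Iterable[tuple],
    features: Sequence[CdsFeature],
    sample: str,
) -> None:
    """Accumulate per-feature counts for ``sample`` from read placements.

    ``placements`` holds ``(read_id, feature_id)`` or
    ``(read_id, feature_id, score)`` tuples. A read placed once counts once;
    a read with several placements counts toward its best-scoring one, and is
    dropped entirely when its best score is tied (or when no scores were
    given and the features differ). Unknown feature ids raise ``KeyError``.
    """
    known = {f.feature_id: f for f in features}
    by_read: dict[str, list[tuple[str, float]]] = {}
    for placement in placements:
        read_id, feature_id = placement[0], placement[1]
        score = float(placement[2]) if len(placement) > 2 else 0.0
        if feature_id not in known:
            raise KeyError(f"placement references unknown feature {feature_id!r}")
        by_read.setdefault(read_id, []).append((feature_id, score))
    counts: dict[str, int] = {fid: 0 for fid in known}
    for read_id, entries in by_read.items():
        distinct = {fid for fid, _ in entries}
        if len(distinct) == 1:
            counts[entries[0][0]] += 1
            continue
        best_score = max(score for _, score in entries)
        best = {fid for fid, score in entries if score == best_score}
        if len(best) == 1:
            counts[best.pop()] += 1
        # tied across features -> dropped
    for feature in features:
        feature.sample_counts[sample] = counts[feature.feature_id]


def read_sam_placements(path: str | Path) -> list[tuple[str, str, float]]:
    """Minimal SAM text ingestion: (read, reference, alignment score) tuples.

    Header lines are skipped, unmapped reads (flag 0x4) dropped, and the
    ``AS:i`` tag used as the score when present (0 otherwise). This is a
    deliberately small reader for count ingestion, not a SAM implementation.
    """
    out: list[tuple[str, str, float]] = []
    with Path(path).open() as handle:
        for line in handle:
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}: SAM line with {len(fields)} fields")
            qname, flag, rname = fields[0], int(fields[1]), fields[2]
            if flag & 0x4 or rname == "*":
                continue
            score = 0.0
            for tag in fields[11:]:
                if tag.startswith("AS:i:"):
                    score = float(tag[5:])
                    break
            out.append((qname, rname, score))
    return out


def tpm(features: Sequence[CdsFeature], sample: str) -> dict[str, float]:
    """TPM values for one sample over the supplied feature set.

    Raises ``ValueError`` when every feature has zero counts (TPM undefined).
    """
    rates = {
        f.feature_id: f.sample_counts.get(sample, 0) / f.length_nt for f in features
    }
    total = sum(rates.values())
    if total == 0:
        raise ValueError(f"no expressed features in sample {sample!r}")
    return {fid: 1e6 * rate / total for fid, rate in rates.items()}


def tpm_table(
    features: Sequence[CdsFeature],
    samples: Sequence[str],
    housekeeping: str | None = None,
    round_dp: int = 3,
) -> TpmTable:
    """TPM over several samples, with housekeeping ratios when requested."""
    values: dict[tuple[str, str], float] = {}
    for sample in samples:
        for fid, v in tpm(features, sample).items():
            values[(fid, sample)] = v
    ratios: dict[tuple[str, str, str], float] = {}
    if housekeeping is not None:
        targets = [f.feature_id for f in features if f.feature_id != housekeeping]
        for sample in samples:
            sample_tpm = {f.feature_id: values[(f.feature_id, sample)] for f in features}
            for fid, ratio in expression_ratio(
                sample_tpm, targets, housekeeping, round_dp
            ).items():
                ratios[(fid, housekeeping, sample)] = ratio
    return TpmTable(samples=tuple(samples), values=values, ratios=ratios)


def expression_ratio(
    tpm_values: Mapping[str, float],
    targets: Sequence[str],
    housekeeping: str,
    round_dp: int = 3,
) -> dict[str, float]:
    """Target/housekeeping TPM ratios, rounded half-even to ``round_dp``.

    Half-even rounding at 3 decimals reproduces published ratio tables.
    Raises ``ValueError`` on a zero (or absent) housekeeping TPM.
    """
    denom = tpm_values.get(housekeeping, 0.0)
    if denom <= 0:
        raise ValueError(f"housekeeping feature {housekeeping!r} has zero TPM")
    return {t: round(tpm_values[t] / denom, round_dp) for t in targets}


def ratio_report(table: TpmTable, path: str | Path) -> Path:
    """Write TPM values and ratios as a TSV mirroring published layouts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.frame()
    ratio_rows = {}
    for (feature, housekeeping, sample), ratio in table.ratios.items():
        ratio_rows.setdefault(f"ratio {feature}/{housekeeping}", {})[sample] = ratio
    for name, row in ratio_rows.items():
        df.loc[name] = [row.get(s, float("nan")) for s in table.samples]
    df.index.name = "feature"
    df.to_csv(path, sep="\t")
    return path
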