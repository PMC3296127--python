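"""Thermodynamic classification of EFM sets and derived flux insights.

Classification runs NET analysis on each mode's reaction-activity sign
pattern.  Feasibility depends only on the sign pattern restricted to
thermodynamically constrained reactions, so verdicts are memoized on that
restriction — large EFM sets share many patterns.  A label journal
(append-only TSV of pattern hash and verdict) makes long classification runs
restartable.

The derived views compare the full and the feasible set: which reaction
directions disappear (condition-specific inactivity/direction predictions),
and how the per-reaction flux ranges per mol substrate shrink.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .efm import EFM, EFMSet, normalize_to_substrate
from .errors import ValidationError
from .model_io import MetabolicModel
from .thermo import ActivityPattern, ConcentrationSet, ThermoData, net_feasibility


def _pattern_hash(key: tuple[tuple[str, int], ...]) -> str:
    return hashlib.sha256(repr(key).encode()).hexdigest()[:20]


@dataclass
class PatternJournal:
    """Append-only verdict store keyed by pattern hash (restartability)."""

    path: Path | None = None
    cache: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "PatternJournal":
        path = Path(path)
        cache = {}
        if path.exists():
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                h, verdict = line.split("\t")
                cache[h] = verdict
        return cls(path=path, cache=cache)

    def get(self, h: str) -> str | None:
        return self.cache.get(h)

    def put(self, h: str, verdict: str) -> None:
        self.cache[h] = verdict
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(f"{h}\t{verdict}\n")


def classify_efm_set(
    efms: EFMSet,
    model: MetabolicModel,
    conc: ConcentrationSet,
    thermo: ThermoData,
    journal: PatternJournal | None = None,
) -> EFMSet:
    """Label every EFM feasible/infeasible/undetermined by NET analysis of
    its sign pattern (memoized; order-independent)."""
    if efms.fingerprint != model.fingerprint():
        raise ValidationError("EFM set was enumerated on a different model")
    journal = journal or PatternJournal()
    labels: list[str] = []
    for efm in efms:
        signs = {
            rid: s for rid, s in efm.sign_pattern().items() if thermo.is_constrained(rid)
        }
        key = ActivityPattern(signs).key()
        h = _pattern_hash(key)
        verdict = journal.get(h)
        if verdict is None:
            verdict = net_feasibility(model, ActivityPattern(signs), conc, thermo).verdict
            journal.put(h, verdict)
        labels.append(verdict)
    return EFMSet(efms=list(efms), fingerprint=efms.fingerprint, labels=labels)


def summarize(efms: EFMSet) -> dict:
    """Counts and fractions; undetermined pooled with feasible
    (conservative)."""
    counts = efms.counts()
    total = counts["total"]
    feasible = counts["feasible"] + counts["undetermined"]
    return {
        **counts,
        "feasible_fraction": feasible / total if total else float("nan"),
        "infeasible_fraction": counts["infeasible"] / total if total else float("nan"),
    }


# ---------------------------------------------------------------------------
# Activity usage
# ---------------------------------------------------------------------------


@dataclass
class ActivityUsageTable:
    """Per reaction: which activities (-1, 0, +1) occur across the full set
    and across the feasible set; flagged reactions lose an activity."""

    full: dict[str, set[int]]
    feasible: dict[str, set[int]]

    def flagged(self) -> dict[str, set[int]]:
        """Reactions whose feasible-set usage lacks an activity present in
        the full set, with the lost activities."""
        out = {}
        for rid, acts in self.full.items():
            lost = acts - self.feasible.get(rid, set())
            if lost:
                out[rid] = lost
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in self.full:
            rows.append(
                {
                    "reaction_id": rid,
                    "full": sorted(self.full[rid]),
                    "feasible": sorted(self.feasible.get(rid, set())),
                    "lost": sorted(self.full[rid] - self.feasible.get(rid, set())),
                }
            )
        return pd.DataFrame(rows)


def _usage(efms: EFMSet, reaction_ids: list[str]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {rid: set() for rid in reaction_ids}
    for efm in efms:
        signs = efm.sign_pattern()
        for rid in reaction_ids:
            out[rid].add(signs.get(rid, 0))
    return out


def compare_activity_usage(full: EFMSet, feasible_subset: EFMSet) -> ActivityUsageTable:
    """Per-reaction activity sets over the full set vs. the feasible set.

    Reactions that lose a direction (or become inactive-only) in the
    feasible set are condition-specific predictions.
    """
    full_supports = {e.support for e in full}
    if any(e.support not in full_supports for e in feasible_subset):
        raise ValidationError("feasible subset contains modes not in the full set")
    rids = sorted({rid for e in full for rid in e.support})
    return ActivityUsageTable(
        full=_usage(full, rids), feasible=_usage(feasible_subset, rids)
    )


# ---------------------------------------------------------------------------
# Normalized flux ranges
# ---------------------------------------------------------------------------


@dataclass
class NormalizedFluxRanges:
    """Per reaction: [min, max] flux per mol substrate over an EFM set."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": list(self.ranges),
                "min_per_substrate": [r[0] for r in self.ranges.values()],
                "max_per_substrate": [r[1] for r in self.ranges.values()],
            }
        )


def compute_flux_ranges(efms: EFMSet, substrate: str) -> NormalizedFluxRanges:
    """Highest and lowest substrate-normalized rate of each reaction over
    the set.  All modes must have nonzero substrate flux (filter internal
    cycles first)."""
    if len(efms) == 0:
        raise ValidationError("empty EFM set")
    rids = sorted({rid for e in efms for rid in e.support})
    ranges = {}
    normalized = [normalize_to_substrate(e, substrate) for e in efms]
    for rid in rids:
        vals = [float(e[rid]) for e in normalized]
        ranges[rid] = (min(vals), max(vals))
    return NormalizedFluxRanges(ranges=ranges)


def export_summary_json(efms: EFMSet, path: str | Path) -> dict:
    summary = summarize(efms)
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
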