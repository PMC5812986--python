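"""Group-label permutation machinery with empirical FDR.

Exhaustive enumeration of labelled two-group assignments, seeded random
relabelling (uniform draws with replacement, mirroring repeated calls to
R's sample()), re-running an injected per-feature test under each
assignment, and the empirical false-discovery ratio: mean discovery
count over null relabellings divided by the observed count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabelAssignment:
    """One labelled sample→group assignment.

    ``composition_class`` summarises, relative to the reference (true)
    grouping, how many samples from a single true group sit together in
    each assigned set — e.g. "4+0" (the true split), "3+1", "2+2" for a
    4-vs-4 design.  ``is_true`` marks the two labelled assignments whose
    partition equals the reference partition.
    """

    samples: Tuple[str, ...]
    labels: Tuple[str, ...]
    composition_class: str
    is_true: bool

    def groups(self) -> Dict[str, str]:
        return dict(zip(self.samples, self.labels))


def _annotate(
    samples: Sequence[str],
    group1_members: frozenset,
    group_names: Tuple[str, str],
    reference_set: frozenset,
    n1: int,
) -> LabelAssignment:
    labels = tuple(group_names[0] if s in group1_members else group_names[1]
                   for s in samples)
    overlap = len(group1_members & reference_set)
    comp = f"{max(overlap, n1 - overlap)}+{min(overlap, n1 - overlap)}"
    # partition equality also needs matching set sizes for unequal designs
    if overlap == len(reference_set):
        is_true = group1_members == reference_set
    elif overlap == 0:
        is_true = group1_members == frozenset(samples) - reference_set
    else:
        is_true = False
    return LabelAssignment(tuple(samples), labels, comp, is_true)


def enumerate_group_assignments(
    samples: Sequence[str],
    sizes: Tuple[int, int],
    group_names: Tuple[str, str] = ("control", "low1C"),
    reference_groups: Optional[Dict[str, str]] = None,
) -> List[LabelAssignment]:
    """All distinct labelled assignments of ``samples`` into two groups.

    There are C(n, n1) of them (both orientations of every partition
    appear when n1 == n2).  ``reference_groups`` defines the true
    grouping used for composition classes; by default the first ``n1``
    samples form the reference first group.
    """
    samples = list(samples)
    n1, n2 = sizes
    if n1 + n2 != len(samples):
        raise ValueError("group sizes must sum to the sample count")
    if reference_groups is None:
        reference_set = frozenset(samples[:n1])
    else:
        first = reference_groups[samples[0]]
        reference_set = frozenset(s for s in samples if reference_groups[s] == first)
        if len(reference_set) != n1:
            # orient the reference so its first group has size n1
            reference_set = frozenset(samples) - reference_set
            if len(reference_set) != n1:
                raise ValueError("reference grouping incompatible with sizes")
    out = []
    for combo in itertools.combinations(samples, n1):
        out.append(_annotate(samples, frozenset(combo), group_names,
                             reference_set, n1))
    return out


def random_assignments(
    samples: Sequence[str],
    sizes: Tuple[int, int],
    n: int = 100,
    seed: int = 0,
    group_names: Tuple[str, str] = ("control", "low1C"),
    reference_groups: Optional[Dict[str, str]] = None,
) -> List[LabelAssignment]:
    """``n`` seeded uniform relabellings (with replacement across draws).

    Each draw permutes the samples and assigns the first ``n1`` to the
    first group.  The true assignment may be drawn; whether it is kept
    in the null set is decided downstream.
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    samples = list(samples)
    n1, n2 = sizes
    if n1 + n2 != len(samples):
        raise ValueError("group sizes must sum to the sample count")
    if reference_groups is None:
        reference_set = frozenset(samples[:n1])
    else:
        first = reference_groups[samples[0]]
        reference_set = frozenset(s for s in samples if reference_groups[s] == first)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        perm = rng.permutation(len(samples))
        members = frozenset(samples[i] for i in perm[:n1])
        out.append(_annotate(samples, members, group_names, reference_set, n1))
    return out


@dataclass
class PermutationSummary:
    """Discovery counts per assignment plus the empirical FDR."""

    observed: int
    counts: pd.DataFrame  # columns: labels, composition_class, is_true, count
    mean_null: float
    empirical_fdr: float
    threshold_kind: str
    threshold: float

    def to_json_dict(self) -> dict:
        return {
            "observed": int(self.observed),
            "mean_null": float(self.mean_null),
            "empirical_fdr": None if np.isnan(self.empirical_fdr)
            else float(self.empirical_fdr),
            "threshold_kind": self.threshold_kind,
            "threshold": self.threshold,
            "assignments": [
                {
                    "labels": list(row.labels),
                    "composition_class": row.composition_class,
                    "is_true": bool(row.is_true),
                    "count": int(row["count"]),
                }
                for _, row in self.counts.iterrows()
            ],
        }


def permutation_discovery_counts(
    data,
    test: Callable[[object, Dict[str, str]], pd.DataFrame],
    threshold_kind: str,
    threshold: float,
    assignments: Sequence[LabelAssignment],
    true_groups: Dict[str, str],
    exclude_true: bool = True,
) -> PermutationSummary:
    """Re-run a per-feature test under every relabelling and count hits.

    ``test(data, groups)`` must return a DataFrame with a column named
    after ``threshold_kind`` ('p' or 'q'); a feature is a discovery when
    that value is strictly below ``threshold``.  The observed count uses
    ``true_groups``.  ``exclude_true`` drops assignments whose partition
    equals the true one from the null mean (set False to mirror sampling
    schemes that keep them).
    """
    if threshold_kind not in ("p", "q"):
        raise ValueError("threshold_kind must be 'p' or 'q'")

    def count_for(groups: Dict[str, str]) -> int:
        res = test(data, groups)
        vals = np.asarray(res[threshold_kind], dtype=float)
        return int(np.nansum(vals < threshold))

    observed = count_for(true_groups)
    rows = []
    for a in assignments:
        rows.append(
            {
                "labels": a.labels,
                "composition_class": a.composition_class,
                "is_true": a.is_true,
                "count": count_for(a.groups()),
            }
        )
    counts = pd.DataFrame(rows)
    null_mask = ~counts["is_true"] if exclude_true else np.ones(len(counts), bool)
    null_counts = counts.loc[null_mask, "count"].to_numpy()
    if len(null_counts) == 0:
        raise ValueError("no null assignments to summarise")
    mean_null = float(null_counts.mean())
    fdr = empirical_fdr(observed, null_counts)
    return PermutationSummary(observed, counts, mean_null, fdr,
                              threshold_kind, threshold)


def empirical_fdr(observed: int, null_counts) -> float:
    """mean(null_counts) / observed; NaN sentinel when observed == 0."""
    null_counts = np.asarray(null_counts, dtype=float)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if observed == 0:
        return float("nan")
    return float(null_counts.mean() / observed)
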