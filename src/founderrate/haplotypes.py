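"""Haplotype collapsing, group counts and group-defining mutations.

Ancient consensus sequences carry undetermined positions (N), so haplotype
identity needs a missing-data policy:

``strict``
    two samples share a haplotype iff they are identical at every unmasked
    column, with N treated as an ordinary mismatching symbol;
``compatible`` (default)
    two samples may share a haplotype iff they agree at every unmasked
    column where both are determined.  Compatibility is not transitive, so
    samples are merged greedily in a documented order — descending count of
    determined unmasked positions, ties broken by sample id — and a sample
    joins the first cluster whose every member it is compatible with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .alignment import AlignedDataset, AlignmentError, DETERMINED


class HaplotypeError(ValueError):
    pass


@dataclass(frozen=True)
class HaplotypeSet:
    """A partition of samples into haplotypes.

    ``assignment`` maps sample_id -> label; ``representatives`` maps label ->
    a consensus sequence over the full alignment (site-wise majority of the
    members' determined bases, N where none is determined).  Masked columns
    are retained in the representative text but ignored downstream.
    """

    assignment: dict[str, str]
    representatives: dict[str, str]
    policy: str

    @property
    def labels(self) -> list[str]:
        return sorted(self.representatives)

    def members(self, label: str) -> list[str]:
        return sorted(s for s, l in self.assignment.items() if l == label)

    def counts(self) -> dict[str, int]:
        return dict(Counter(self.assignment.values()))


def _compatible(a: str, b: str, cols: np.ndarray) -> bool:
    for i in cols:
        ca, cb = a[i], b[i]
        if ca != cb and ca in DETERMINED and cb in DETERMINED:
            return False
    return True


def _strict_key(seq: str, cols: np.ndarray) -> str:
    return "".join(seq[i] for i in cols)


def _majority_consensus(seqs: list[str], L: int) -> str:
    out = []
    for i in range(L):
        states = [s[i] for s in seqs if s[i] in DETERMINED]
        if not states:
            out.append("N")
        else:
            # majority; ties broken toward the state seen first in merge order
            counts = Counter(states)
            top = max(counts.values())
            for st in states:
                if counts[st] == top:
                    out.append(st)
                    break
    return "".join(out)


def collapse_haplotypes(
    ds: AlignedDataset,
    missing_policy: str = "compatible",
    label_prefix=None,
) -> HaplotypeSet:
    """Partition the samples of an aligned dataset into haplotypes.

    ``label_prefix`` optionally maps sample_id -> a one-letter group prefix
    (e.g. W for island, S for mainland); each cluster is labelled with the
    prefix of its first member plus an ordinal in order of cluster creation
    within that prefix.  Without it, labels are ``H1, H2, ...``.
    """
    if missing_policy not in ("compatible", "strict"):
        raise HaplotypeError(f"unknown missing-data policy {missing_policy!r}")
    cols = ds.unmasked_columns()
    seqs = dict(ds.records)

    if missing_policy == "strict":
        clusters: dict[str, list[str]] = {}
        order = sorted(seqs)  # deterministic; strict keying is order-free
        for sid in order:
            clusters.setdefault(_strict_key(seqs[sid], cols), []).append(sid)
        groups = [sorted(m) for m in clusters.values()]
        groups.sort(key=lambda m: m[0])
    else:
        # documented greedy order: most-complete first, then id
        def completeness(sid):
            s = seqs[sid]
            return sum(1 for i in cols if s[i] in DETERMINED)

        order = sorted(seqs, key=lambda sid: (-completeness(sid), sid))
        groups = []
        for sid in order:
            for members in groups:
                if all(_compatible(seqs[sid], seqs[m], cols) for m in members):
                    members.append(sid)
                    break
            else:
                groups.append([sid])

    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    counters: Counter = Counter()
    for members in groups:
        prefix = "H" if label_prefix is None else label_prefix.get(members[0], "H")
        counters[prefix] += 1
        label = f"{prefix}{counters[prefix]}"
        for m in members:
            assignment[m] = label
        representatives[label] = _majority_consensus([seqs[m] for m in members], ds.length)
    return HaplotypeSet(assignment=assignment, representatives=representatives,
                        policy=missing_policy)


def summarize_groups(table, predicate=None, label_col: str = "haplotype") -> int:
    """Count distinct haplotype labels among rows matching ``predicate``.

    ``table`` is a DataFrame carrying one row per sample with a haplotype
    label column (either from :func:`collapse_haplotypes` or a published
    label column); ``predicate`` is a boolean mask or a callable on the
    frame.  Returns 0 (with a warning) when nothing matches.
    """
    if isinstance(table, dict):
        table = pd.DataFrame({label_col: pd.Series(table)})
    rows = table if predicate is None else table[
        predicate(table) if callable(predicate) else predicate
    ]
    if len(rows) == 0:
        warnings.warn("group predicate matches no samples", stacklevel=2)
        return 0
    return int(rows[label_col].nunique())


@dataclass(frozen=True)
class Synapomorphy:
    """A site where a fixed, group-exclusive state separates the group.

    ``site`` is 0-based (alignment coordinate); ``site1`` gives the 1-based
    position for reporting.  ``other_state`` is the majority state among the
    determined non-group samples.
    """

    site: int
    group_state: str
    other_state: str
    group_determined_frac: float

    @property
    def site1(self) -> int:
        return self.site + 1


def find_synapomorphies(
    ds: AlignedDataset,
    group_ids,
    min_determined_frac: float = 1.0,
) -> tuple[list[Synapomorphy], list[Synapomorphy]]:
    """Sites with a derived state fixed in the group and absent outside it.

    A site qualifies when (a) every determined group member shares one
    state, (b) no determined non-group member carries that state, and
    (c) at least ``min_determined_frac`` of the group is determined there.
    Sites passing (a)-(b) but failing (c) are returned separately as
    incomplete candidates.  Returns ``(confirmed, candidates)``.
    """
    group = set(group_ids)
    ids = set(ds.sample_ids)
    unknown = group - ids
    if unknown:
        raise HaplotypeError(f"group ids not in dataset: {sorted(unknown)}")
    if not group:
        raise HaplotypeError("group is empty")
    if group == ids:
        raise HaplotypeError("group must be a proper subset of the samples")
    seqs = dict(ds.records)
    group_seqs = [seqs[s] for s in sorted(group)]
    other_seqs = [seqs[s] for s in sorted(ids - group)]
    confirmed: list[Synapomorphy] = []
    candidates: list[Synapomorphy] = []
    n_group = len(group_seqs)
    for i in ds.unmasked_columns():
        gstates = [s[i] for s in group_seqs if s[i] in DETERMINED]
        if not gstates:
            continue
        state = gstates[0]
        if any(st != state for st in gstates):
            continue
        ostates = [s[i] for s in other_seqs if s[i] in DETERMINED]
        if not ostates or state in ostates:
            continue
        other = Counter(ostates).most_common(1)[0][0]
        rec = Synapomorphy(
            site=int(i),
            group_state=state,
            other_state=other,
            group_determined_frac=len(gstates) / n_group,
        )
        if rec.group_determined_frac >= min_determined_frac:
            confirmed.append(rec)
        else:
            candidates.append(rec)
    return confirmed, candidates
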