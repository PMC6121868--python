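"""Haplotype collapsing, group counts and synapomorphy detection."""

import itertools

import numpy as np
import pytest

import founderrate as fr
from founderrate.alignment import DETERMINED
from founderrate.haplotypes import HaplotypeError


def test_identical_sequences_collapse_to_one(make_dataset):
    ds = make_dataset({f"s{i}": "ACGTACGT" for i in range(5)})
    haps = fr.collapse_haplotypes(ds)
    assert len(haps.representatives) == 1
    assert set(haps.assignment.values()) == {"H1"}


def test_single_difference_makes_two_haplotypes(make_dataset):
    ds = make_dataset({"a": "ACGT", "b": "ACGA"})
    assert len(fr.collapse_haplotypes(ds).representatives) == 2
    assert len(fr.collapse_haplotypes(ds, "strict").representatives) == 2


def test_compatible_policy_handles_missing_data(make_dataset):
    # B is A with one undetermined site; C differs from A exactly there
    ds = make_dataset({"A": "ACGTACGT", "B": "ACGNACGT", "C": "ACGGACGT"})
    haps = fr.collapse_haplotypes(ds, "compatible")
    groups = {}
    for sid, label in haps.assignment.items():
        groups.setdefault(label, set()).add(sid)
    assert sorted(map(sorted, groups.values())) == [["A", "B"], ["C"]]
    # strict: N never matches, three haplotypes
    assert len(fr.collapse_haplotypes(ds, "strict").representatives) == 3


def test_compatibility_is_not_transitive_but_order_is_documented(make_dataset):
    """Brute force over merge orders shows the A/B/C case is order-dependent;
    the implementation's completeness-then-id order fixes the outcome."""
    seqs = {"A": "ACGTACGT", "B": "ACGNACGT", "C": "ACGGACGT"}

    def greedy(order):
        groups = []
        for sid in order:
            for g in groups:
                if all(
                    all(
                        x == y or x not in DETERMINED or y not in DETERMINED
                        for x, y in zip(seqs[sid], seqs[m])
                    )
                    for m in g
                ):
                    g.append(sid)
                    break
            else:
                groups.append([sid])
        return sorted(tuple(sorted(g)) for g in groups)

    outcomes = {tuple(greedy(order)) for order in itertools.permutations(seqs)}
    assert len(outcomes) > 1  # the non-transitivity is real
    ds = make_dataset(seqs)
    haps = fr.collapse_haplotypes(ds, "compatible")
    assert haps.assignment["A"] == haps.assignment["B"] != haps.assignment["C"]


def test_strict_collapse_invariant_under_reordering(make_dataset):
    seqs = {"a": "ACGT", "b": "ACGA", "c": "ACGT", "d": "NCGT"}
    counts = set()
    for order in itertools.permutations(seqs):
        ds = make_dataset({k: seqs[k] for k in order})
        counts.add(len(fr.collapse_haplotypes(ds, "strict").representatives))
    assert counts == {3}


def test_unknown_policy_rejected(make_dataset):
    ds = make_dataset({"a": "ACGT"})
    with pytest.raises(HaplotypeError):
        fr.collapse_haplotypes(ds, "fuzzy")


def test_label_prefixes_follow_groups(make_dataset):
    ds = make_dataset({"w1": "ACGT", "w2": "ACGT", "s1": "ACGA"})
    prefixes = {"w1": "W", "w2": "W", "s1": "S"}
    haps = fr.collapse_haplotypes(ds, label_prefix=prefixes)
    assert haps.assignment["w1"] == haps.assignment["w2"] == "W1"
    assert haps.assignment["s1"] == "S1"


def test_summarize_groups_counts_distinct_labels(table1):
    assert fr.summarize_groups(table1) == 34
    n_hol = fr.summarize_groups(
        table1,
        lambda t: (t.location == "Wrangel Island") & (t.median_calBP < 10_000),
    )
    assert n_hol == 7
    with pytest.warns(UserWarning):
        assert fr.summarize_groups(table1, lambda t: t.location == "Mars") == 0


def test_masking_never_increases_haplotype_count(make_dataset):
    rng = np.random.default_rng(4)
    L = 30
    seqs = {
        f"s{i}": "".join("ACGT"[b] for b in rng.integers(4, size=L))
        for i in range(8)
    }
    ds = make_dataset(seqs)
    prev = len(fr.collapse_haplotypes(ds).representatives)
    masked = ds
    for start in range(1, L, 5):
        masked = fr.mask_region(masked, [(start, min(start + 3, L))])
        cur = len(fr.collapse_haplotypes(masked).representatives)
        assert cur <= prev
        prev = cur


def test_synapomorphies_on_planted_dataset(star_dataset):
    from founderrate import synth

    ds, _ = star_dataset
    group = ds.sample_ids[:5]
    ann = synth.synthetic_annotation(ds.length)
    records, truths = synth.plant_synapomorphies(
        list(ds.records), group,
        [("trna_val", "tRNA"), ("cds_fwd", "synonymous"), ("cds_rev", "nonsynonymous")],
        ann, seed=8,
    )
    ds2 = fr.AlignedDataset(records=tuple(records), metadata=ds.metadata)
    confirmed, candidates = fr.find_synapomorphies(ds2, group)
    assert {(c.site, c.group_state, c.other_state) for c in confirmed} == {
        (t.site, t.group_state, t.other_state) for t in truths
    }
    assert candidates == []


def test_no_variation_or_shared_outsider_yields_nothing(make_dataset):
    ds = make_dataset({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
    confirmed, candidates = fr.find_synapomorphies(ds, ["a", "b"])
    assert confirmed == [] and candidates == []
    # one outsider shares the would-be group state: excluded
    ds2 = make_dataset({"a": "ACGA", "b": "ACGA", "c": "ACGT", "d": "ACGA"})
    confirmed, _ = fr.find_synapomorphies(ds2, ["a", "b"])
    assert confirmed == []


def test_synapomorphy_group_validation(make_dataset):
    ds = make_dataset({"a": "ACGT", "b": "ACGA"})
    with pytest.raises(HaplotypeError):
        fr.find_synapomorphies(ds, ["a", "b"])
    with pytest.raises(HaplotypeError):
        fr.find_synapomorphies(ds, [])
    with pytest.raises(HaplotypeError):
        fr.find_synapomorphies(ds, ["z"])


def test_incomplete_group_sites_reported_separately(make_dataset):
    ds = make_dataset({"a": "ACGA", "b": "NCGA", "c": "TCGT"})
    confirmed, candidates = fr.find_synapomorphies(ds, ["a", "b"], 1.0)
    assert [c.site for c in confirmed] == [3]
    assert [c.site for c in candidates] == [0]
    assert candidates[0].group_determined_frac == 0.5
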