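"""Synthetic inputs: the packaged sample-metadata table, star-like
alignments with planted group-exclusive mutations, and serially sampled
datasets simulated at known parameters for parameter-recovery tests.

Every generator records enough truth to recompute the expected downstream
answer exactly, and is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .alignment import AlignedDataset
from .coalescent import count_haplotypes, drop_mutations, simulate_genealogy
from .coding import GeneAnnotation, Feature, classify_coding_effect
from .models import BASES, MutationModel, PopulationModel
from .schedule import build_schedule


class SynthesisError(ValueError):
    pass


# ---------------------------------------------------------------- fixture

def table1_fixture() -> pd.DataFrame:
    """The packaged 42-sample metadata table (ids, radiocarbon dates, median
    calibrated ages, locations and published haplotype labels).

    Samples dated only by bounds or ranges carry a missing ``median_calBP``
    and are excluded by any age predicate.
    """
    with resources.files("founderrate.data").joinpath("table1.tsv").open("rb") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"sample_id": str})
    df["median_calBP"] = pd.to_numeric(df["median_calBP"], errors="coerce")
    return df


def holocene_wrangel_rows(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows of the fixture from the island population younger than 10 kyr."""
    if df is None:
        df = table1_fixture()
    return df[(df["location"] == "Wrangel Island") & (df["median_calBP"] < 10_000)]


# ----------------------------------------------------- serial coalescent data

@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset, sufficient to recompute every
    downstream expected answer."""

    seed: int
    mu: float | None = None
    n_females: float | None = None
    k_true: int | None = None
    signatures: dict | None = None
    assignment: dict | None = None
    planted: tuple = ()


def generate_serial_dataset(
    mu: float,
    n_females: float,
    ages,
    L: int = 16_506,
    t_iso: float = 12_000.0,
    kappa: float = 1.0 / 3.0,
    seed: int = 0,
    generation_time: float = 15.0,
):
    """Simulate one serially sampled dataset under the founder-coalescent.

    Returns ``(records, metadata, truth)`` where ``records`` is a list of
    ``(sample_id, sequence)`` (finite-sites realization relative to an all-A
    founder) and ``metadata`` a frame with sample ages.
    """
    schedule = build_schedule(ages, generation_time)
    pop = PopulationModel(n_females=n_females, t_iso_calBP=t_iso)
    mut = MutationModel(mu_per_site_year=mu, L=L, transition_prob=kappa,
                        sites_mode="finite")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xD5)))
    gen = simulate_genealogy(schedule, pop, rng)
    tips = drop_mutations(gen, mut, rng)
    seqs = tips.sequences()
    records = [(sid, seqs[sid]) for sid in schedule.sample_ids]
    metadata = pd.DataFrame(
        {
            "sample_id": schedule.sample_ids,
            "age_calBP": schedule.ages,
            "location": "synthetic",
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        mu=mu,
        n_females=n_females,
        k_true=count_haplotypes(tips),
        signatures=dict(tips.signatures),
    )
    return records, metadata, truth


# ------------------------------------------------------------ star alignment

def generate_star_alignment(
    n_samples: int,
    n_haplotypes: int,
    max_steps: int = 2,
    L: int = 900,
    seed: int = 0,
):
    """A modal haplotype plus satellites at <= ``max_steps`` mutations.

    Satellite i carries ``1 + (i % max_steps)`` substitutions at globally
    distinct sites, so pairwise distances are exact step sums.  Sample
    multiplicities put the surplus on the modal haplotype.  Returns
    ``(records, truth)``; truth maps sample ids to haplotype indices.
    """
    if n_haplotypes > n_samples:
        raise SynthesisError("n_haplotypes cannot exceed n_samples")
    if n_haplotypes < 1 or max_steps < 1:
        raise SynthesisError("need n_haplotypes >= 1 and max_steps >= 1")
    n_sat = n_haplotypes - 1
    steps = [1 + (i % max_steps) for i in range(n_sat)]
    if sum(steps) > L:
        raise SynthesisError(
            f"sequence length {L} too short for {sum(steps)} distinct mutated sites"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0x57A2)))
    founder = rng.integers(4, size=L)
    free_sites = list(rng.permutation(L))
    hap_seqs = ["".join(BASES[b] for b in founder)]
    for s in steps:
        seq = founder.copy()
        for _ in range(s):
            site = free_sites.pop()
            seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
        hap_seqs.append("".join(BASES[b] for b in seq))
    # multiplicities: modal haplotype absorbs the surplus samples
    mult = [n_samples - n_sat] + [1] * n_sat
    records, assignment = [], {}
    k = 0
    for h, (seq, m) in enumerate(zip(hap_seqs, mult)):
        for _ in range(m):
            sid = f"s{k:02d}"
            records.append((sid, seq))
            assignment[sid] = h
            k += 1
    truth = SyntheticTruth(seed=seed, k_true=n_haplotypes, assignment=assignment,
                           planted=tuple(steps))
    return records, truth


# ------------------------------------------------------- planted mutations

def synthetic_annotation(L: int = 900) -> GeneAnnotation:
    """A miniature mitogenome-like layout: two CDS on opposite strands, a
    tRNA, an rRNA and noncoding spacers, so strand handling is exercised."""
    if L < 850:
        raise SynthesisError("synthetic annotation needs an alignment of >= 850 bp")
    feats = (
        Feature(name="cds_fwd", start=30, end=330, strand="+", feature_class="CDS"),
        Feature(name="trna_val", start=340, end=410, strand="+", feature_class="tRNA"),
        Feature(name="rrna_small", start=420, end=540, strand="+", feature_class="rRNA"),
        Feature(name="cds_rev", start=550, end=850, strand="-", feature_class="CDS"),
    )
    return GeneAnnotation(features=feats, alignment_length=L)


@dataclass(frozen=True)
class PlantedMutation:
    site: int  # 0-based alignment position
    group_state: str
    other_state: str
    feature: str
    effect_class: str


def plant_synapomorphies(
    records,
    group_ids,
    wanted,
    annotation: GeneAnnotation,
    seed: int = 0,
):
    """Insert group-exclusive substitutions with requested coding effects.

    ``wanted`` is a list of ``(feature_name, desired_class)`` with class in
    {tRNA, rRNA, synonymous, nonsynonymous}.  Only alignment columns that
    are invariant and determined across all samples are eligible, so each
    planted state is exclusive to and fixed within the group by
    construction.  Returns ``(new_records, truths)``.
    """
    group = set(group_ids)
    ids = [sid for sid, _ in records]
    if not group:
        raise SynthesisError("group is empty")
    if not group.issubset(ids):
        raise SynthesisError("group ids must be present in the records")
    if group == set(ids):
        raise SynthesisError("group must be a proper subset of the samples")
    seqs = {sid: list(seq) for sid, seq in records}
    L = len(records[0][1])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xA17)))
    used: set[int] = set()
    truths: list[PlantedMutation] = []
    features = {f.name: f for f in annotation.features}
    for feature_name, desired in wanted:
        if feature_name not in features:
            raise SynthesisError(f"no feature named {feature_name!r}")
        f = features[feature_name]
        sites = [
            s for s in rng.permutation(np.arange(f.start, f.end))
            if s not in used and len({seqs[sid][s] for sid in ids}) == 1
            and seqs[ids[0]][s] in "ACGT"
        ]
        planted = None
        for site in sites:
            site = int(site)
            anc = seqs[ids[0]][site]
            for new in rng.permutation([b for b in "ACGT" if b != anc]):
                background = "".join(seqs[ids[0]])
                recs = classify_coding_effect(site, str(new), anc, annotation, background)
                match = [r for r in recs if r.feature == feature_name
                         and r.effect_class == desired]
                if match:
                    planted = PlantedMutation(
                        site=site, group_state=str(new), other_state=anc,
                        feature=feature_name, effect_class=desired,
                    )
                    break
            if planted:
                break
        if planted is None:
            raise SynthesisError(
                f"no invariant site in {feature_name!r} can yield a "
                f"{desired} change"
            )
        used.add(planted.site)
        for sid in group:
            seqs[sid][planted.site] = planted.group_state
        truths.append(planted)
    new_records = [(sid, "".join(seqs[sid])) for sid in ids]
    return new_records, truths


# ------------------------------------------------------------------ writers

def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
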