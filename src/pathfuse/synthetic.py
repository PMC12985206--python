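"""Synthetic pathway-structured tri-omics cohorts with planted class signal.

The generator states a small but realistic desk-scale world: 400 patients,
500 genes organized into 20 disjoint leaf pathways under a two-level toy
hierarchy, binary class labels at a 50/50 balance, and a single driver
pathway whose member genes carry the class signal in one modality —
additively on (log-scale) expression, multiplicatively on mutation odds,
and additively on a latent copy-number dosage that is discretized to
GISTIC-style calls in {-2,...,2}.  Everything is reproducible from the
seed, and the written GMT/relations/TSV files round-trip through the same
loaders the real-data paths use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import PathwayHierarchy, build_hierarchy
from .preprocess import OmicsMatrix

__all__ = ["SyntheticSpec", "SyntheticCohort", "make_toy_hierarchy", "simulate_cohort",
           "corrupt_labels"]


@dataclass
class SyntheticSpec:
    """Stated world for the synthetic cohort generator."""

    n_samples: int = 400
    n_genes: int = 500
    n_leaf_pathways: int = 20
    genes_per_pathway: int = 25
    n_levels: int = 2  # pathway levels above genes
    leaves_per_parent: int = 2
    overlap_fraction: float = 0.0
    driver_pathways: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("LP01", "expression", 3.0)]
    )
    class_balance: float = 0.5
    noise_sd: float = 1.0
    expression_baseline: float = 5.0
    mutation_base_rate: float = 0.05
    cnv_states: tuple[int, ...] = (-2, -1, 0, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.genes_per_pathway * self.n_leaf_pathways > self.n_genes:
            raise ValueError(
                "genes_per_pathway * n_leaf_pathways exceeds n_genes"
            )
        for _, modality, effect in self.driver_pathways:
            if not np.isfinite(effect):
                raise ValueError("effect sizes must be finite")
            if modality not in ("expression", "cnv", "snv"):
                raise ValueError(f"unknown driver modality {modality!r}")


@dataclass
class SyntheticCohort:
    expression: OmicsMatrix
    cnv: OmicsMatrix
    snv: OmicsMatrix
    labels: pd.Series  # patient short-ID -> {0,1}
    drivers: list[dict]  # ground truth: pathway, modality, effect, member genes

    @property
    def matrices(self) -> dict[str, OmicsMatrix]:
        return {"expression": self.expression, "cnv": self.cnv, "snv": self.snv}


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def make_toy_hierarchy(
    spec: SyntheticSpec, out_dir=None
) -> tuple[PathwayHierarchy, set[tuple[str, str]], set[tuple[str, str]]]:
    """Build (and optionally write) a layered toy pathway prior.

    Genes fill leaf pathways disjointly (plus an optional overlap fraction
    of extra, already-assigned genes per pathway); leaves are grouped under
    parents level by level up to the roots.  Returns the hierarchy plus the
    raw membership/relation pair sets.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [_gene_name(i) for i in range(spec.n_genes)]
    leaves = [f"LP{i + 1:02d}" for i in range(spec.n_leaf_pathways)]
    membership: set[tuple[str, str]] = set()
    for pi, leaf in enumerate(leaves):
        start = pi * spec.genes_per_pathway
        members = genes[start:start + spec.genes_per_pathway]
        for g in members:
            membership.add((g, leaf))
        if spec.overlap_fraction > 0:
            n_extra = int(round(spec.overlap_fraction * spec.genes_per_pathway))
            pool = [g for g in genes[: spec.n_leaf_pathways * spec.genes_per_pathway]
                    if (g, leaf) not in membership]
            for g in rng.choice(pool, size=min(n_extra, len(pool)), replace=False):
                membership.add((str(g), leaf))

    relations: set[tuple[str, str]] = set()
    current = leaves
    for level in range(1, spec.n_levels):
        tag = "TP" if level == spec.n_levels - 1 else f"M{level}P"
        n_parents = max(1, int(np.ceil(len(current) / spec.leaves_per_parent)))
        parents = [f"{tag}{i + 1:02d}" for i in range(n_parents)]
        for i, child in enumerate(current):
            relations.add((child, parents[i // spec.leaves_per_parent]))
        current = parents

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_set: dict[str, list[str]] = {}
        for g, p in sorted(membership):
            by_set.setdefault(p, []).append(g)
        with open(out_dir / "pathways.gmt", "w") as fh:
            for p in sorted(by_set):
                fh.write("\t".join([p, "toy pathway"] + by_set[p]) + "\n")
        with open(out_dir / "relations.tsv", "w") as fh:
            for c, p in sorted(relations):
                fh.write(f"{c}\t{p}\n")
    hierarchy = build_hierarchy(membership, relations, n_levels=spec.n_levels)
    return hierarchy, membership, relations


def simulate_cohort(spec: SyntheticSpec, hierarchy: PathwayHierarchy) -> SyntheticCohort:
    """Draw a labeled tri-omics cohort with the spec's planted drivers."""
    members = {}
    for g, p in hierarchy.gene_membership:
        members.setdefault(p, set()).add(g)
    for pathway, _, _ in spec.driver_pathways:
        if pathway not in members:
            raise ValueError(f"driver pathway {pathway!r} not in hierarchy")

    rng = np.random.default_rng(spec.seed)
    samples = [f"SYN-{i + 1:04d}" for i in range(spec.n_samples)]
    genes = [_gene_name(i) for i in range(spec.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    y = (rng.uniform(size=spec.n_samples) < spec.class_balance).astype(int)

    def driver_cols(modality: str) -> tuple[np.ndarray, np.ndarray]:
        shift = np.zeros(spec.n_genes)
        for pathway, mod, effect in spec.driver_pathways:
            if mod != modality:
                continue
            for g in members[pathway]:
                if g in gene_index:
                    shift[gene_index[g]] += effect
        return shift

    # expression: additive effect on a log-scale abundance
    shift = driver_cols("expression")
    expr = (
        spec.expression_baseline
        + y[:, None] * shift[None, :]
        + rng.normal(0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    )
    expr = np.clip(expr, 0.0, None)

    # cnv: latent dosage shifted by the driver effect, discretized to calls
    shift = driver_cols("cnv")
    latent = y[:, None] * shift[None, :] + rng.normal(0, 1.0, size=expr.shape)
    edges = [-2.5, -1.2, 1.2, 2.5]  # boundaries between the 5 GISTIC-like states
    states = np.asarray(spec.cnv_states, dtype=float)
    cnv = states[np.searchsorted(np.asarray(edges), latent)]

    # snv: driver effect acts multiplicatively on mutation odds
    shift = driver_cols("snv")
    base_odds = spec.mutation_base_rate / (1 - spec.mutation_base_rate)
    odds = base_odds * np.exp(y[:, None] * shift[None, :])
    p_mut = odds / (1 + odds)
    snv = (rng.uniform(size=expr.shape) < p_mut).astype(float)

    labels = pd.Series(y, index=samples, name="label")
    drivers = [
        {"pathway": p, "modality": m, "effect": e, "genes": sorted(members[p])}
        for p, m, e in spec.driver_pathways
    ]
    return SyntheticCohort(
        expression=OmicsMatrix(samples, genes, expr, "expression"),
        cnv=OmicsMatrix(samples, genes, cnv, "cnv"),
        snv=OmicsMatrix(samples, genes, snv, "snv"),
        labels=labels,
        drivers=drivers,
    )


def corrupt_labels(cohort: SyntheticCohort, seed: int = 0) -> SyntheticCohort:
    """Permute the label assignment (multiset preserved); omics untouched."""
    rng = np.random.default_rng(seed)
    permuted = pd.Series(
        rng.permutation(cohort.labels.to_numpy()),
        index=cohort.labels.index,
        name=cohort.labels.name,
    )
    return SyntheticCohort(cohort.expression, cohort.cnv, cohort.snv, permuted,
                           cohort.drivers)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort in the on-disk formats the real-data loaders consume.

    Expression is stored as raw non-negative values (expm1 of the log-scale
    matrix) so the standard log1p loader recovers the simulated values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.expm1(cohort.expression.to_frame()).to_csv(out_dir / "expression.tsv", sep="\t")
    cohort.cnv.to_frame().to_csv(out_dir / "cnv.tsv", sep="\t")
    rows = []
    snv = cohort.snv
    for si, sample in enumerate(snv.sample_ids):
        for gi in np.flatnonzero(snv.values[si]):
            rows.append((sample, snv.gene_ids[gi], "Missense_Mutation", 20))
    pd.DataFrame(
        rows,
        columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification",
                 "t_alt_count"],
    ).to_csv(out_dir / "mutations.maf.tsv", sep="\t", index=False)
    clin = pd.DataFrame(
        {
            "patient_id": cohort.labels.index,
            "stage_T": np.where(cohort.labels.to_numpy() == 1, "T3", "T1"),
            "stage_N": np.where(cohort.labels.to_numpy() == 1, "N1", "N0"),
            "stage_M": np.where(cohort.labels.to_numpy() == 1, "M1", "M0"),
        }
    )
    clin.to_csv(out_dir / "clinical.tsv", sep="\t", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump({"drivers": cohort.drivers}, fh, indent=1)
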