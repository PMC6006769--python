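"""Summary statistics over classified proteins and their genomes.

Produces the per-species presence/absence matrix of subclasses, coverage
percentages (fraction of species with at least one member of each subclass
or class), intra-genome copy numbers, and the association between carrying
a tnpA_Y1-like gene and genome size (two-sided Wilcoxon rank-sum test;
genome sizes are skewed, so a rank-based test is used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .homolog_pipeline import SubclassLabel

__all__ = [
    "PresenceMatrix",
    "build_presence_matrix",
    "coverage_stats",
    "copy_number",
    "genome_size_association",
    "plot_presence_heatmap",
]


@dataclass
class PresenceMatrix:
    """Species x subclass boolean presence plus genome sizes (Mb).

    ``presence`` is indexed by species_id with one boolean column per
    subclass; ``genome_sizes`` maps species_id -> size in Mb of the single
    representative strain.
    """

    presence: pd.DataFrame
    genome_sizes: pd.Series


def _one_strain_per_species(genomes: pd.DataFrame) -> pd.DataFrame:
    """One representative strain per species: the lexicographically first
    genome_id (a declared convention; any deterministic rule would do)."""
    return (
        genomes.sort_values("genome_id").groupby("species_id", sort=True).first()
    )


def build_presence_matrix(
    labels: list[SubclassLabel],
    protein_genomes: dict[str, str],
    genomes: pd.DataFrame,
) -> PresenceMatrix:
    """Assemble the presence/absence matrix.

    ``genomes`` needs columns ``genome_id``, ``species_id``, ``size_mb``.
    Only the representative strain of each species contributes; discarded
    labels never count.
    """
    required = {"genome_id", "species_id", "size_mb"}
    if not required <= set(genomes.columns):
        raise ValueError(f"genomes table needs columns {sorted(required)}")
    reps = _one_strain_per_species(genomes)
    rep_genomes = set(reps["genome_id"])
    genome_species = dict(zip(genomes["genome_id"], genomes["species_id"]))
    subclasses = sorted(
        {lab.subclass_id for lab in labels if lab.subclass_id is not None}
    )
    presence = pd.DataFrame(
        False, index=reps.index, columns=subclasses, dtype=bool
    )
    for lab in labels:
        if lab.provenance == "discarded" or lab.subclass_id is None:
            continue
        genome = protein_genomes.get(lab.protein_id)
        if genome not in rep_genomes:
            continue
        presence.loc[genome_species[genome], lab.subclass_id] = True
    sizes = pd.Series(reps["size_mb"].to_numpy(), index=reps.index, name="size_mb")
    return PresenceMatrix(presence=presence, genome_sizes=sizes)


def coverage_stats(matrix: PresenceMatrix) -> pd.DataFrame:
    """Percent of species with >= 1 member, per subclass, per class and for
    the no-member fraction.  ``none`` and ``any`` sum to 100."""
    presence = matrix.presence
    n_species = len(presence)
    if n_species == 0:
        raise ValueError("empty presence matrix")
    rows = []
    for sub in presence.columns:
        rows.append(("subclass", sub, 100.0 * presence[sub].sum() / n_species))
    classes = sorted({c.split(".")[0] for c in presence.columns})
    for cls in classes:
        cols = [c for c in presence.columns if c.split(".")[0] == cls]
        any_cls = presence[cols].any(axis=1)
        rows.append(("class", cls, 100.0 * any_cls.sum() / n_species))
    any_at_all = presence.any(axis=1)
    rows.append(("any", "any", 100.0 * any_at_all.sum() / n_species))
    rows.append(("none", "none", 100.0 * (~any_at_all).sum() / n_species))
    return pd.DataFrame(rows, columns=["level", "group", "pct_species"])


def copy_number(
    labels: list[SubclassLabel], protein_genomes: dict[str, str]
) -> pd.DataFrame:
    """Counts of non-discarded labels per (genome, subclass)."""
    rows = [
        (protein_genomes[lab.protein_id], lab.subclass_id)
        for lab in labels
        if lab.provenance != "discarded" and lab.subclass_id is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["genome_id", "subclass", "count"])
    df = pd.DataFrame(rows, columns=["genome_id", "subclass"])
    out = (
        df.value_counts(["genome_id", "subclass"])
        .rename("count")
        .reset_index()
        .sort_values(["genome_id", "subclass"])
        .reset_index(drop=True)
    )
    return out


def genome_size_association(
    matrix: PresenceMatrix, exclude_subclasses: list[str] | None = None
) -> tuple[float, float, tuple[float, float]]:
    """Compare genome sizes of species carrying >= 1 member (after
    excluding ``exclude_subclasses``, e.g. the IS-like subclass) against
    species carrying none.

    Returns ``(rank-sum statistic, two-sided p-value, (mean_with,
    mean_without))`` from a Wilcoxon rank-sum (Mann-Whitney U) test.
    """
    presence = matrix.presence
    cols = [c for c in presence.columns if c not in set(exclude_subclasses or [])]
    carriers = presence[cols].any(axis=1) if cols else pd.Series(False, index=presence.index)
    sizes = matrix.genome_sizes
    with_sizes = sizes[carriers].to_numpy(dtype=float)
    without_sizes = sizes[~carriers].to_numpy(dtype=float)
    if len(with_sizes) < 2 or len(without_sizes) < 2:
        raise ValueError("need >= 2 species in each group")
    res = stats.mannwhitneyu(with_sizes, without_sizes, alternative="two-sided")
    return (
        float(res.statistic),
        float(res.pvalue),
        (float(np.mean(with_sizes)), float(np.mean(without_sizes))),
    )


def plot_presence_heatmap(matrix: PresenceMatrix, path) -> None:
    """Black-band presence/absence heat map (species x subclass), one row
    per species ordered by genome size.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = matrix.genome_sizes.sort_values(ascending=False).index
    data = matrix.presence.loc[order].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1 + 0.4 * matrix.presence.shape[1], 2 + 0.05 * len(order))
    )
    ax.imshow(data, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(matrix.presence.shape[1]))
    ax.set_xticklabels(matrix.presence.columns, rotation=90)
    ax.set_yticks([])
    ax.set_xlabel("subclass")
    ax.set_ylabel("species (by genome size)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
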