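"""Experimental design generation for pure-stand / binary-mixture pot trials.

The layout mirrors a randomized complete block design within treatment:
every pure stand (six plants of one genotype per pot) and every binary
mixture (two genotypes in alternating positions, three plants each) is
replicated once per block within each treatment, controls are monogenotypic
pots of a single commercial check variety, and harvests are staggered so
that within each block x treatment combination the pots are split evenly
across harvest dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PLANTS_PER_POT = 6
CONTROL_GENOTYPE = "CONTROL"

DESIGN_COLUMNS = [
    "tube_id",
    "treatment",
    "block",
    "harvest_date",
    "is_control",
    "is_mixture",
    *[f"pos{i}" for i in range(1, PLANTS_PER_POT + 1)],
]


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype of the panel.

    intrinsic_root_area is the potential pure-stand per-plant projected root
    area (mm^2); baseline_vigor is a dimensionless standardized log-area
    score used by the trait simulator.
    """

    genotype_id: str
    intrinsic_root_area: float
    baseline_vigor: float = 0.0

    def __post_init__(self) -> None:
        if not self.intrinsic_root_area > 0:
            raise ValueError(
                f"intrinsic_root_area must be > 0, got {self.intrinsic_root_area}"
            )


def _genotype_labels(genotypes) -> list[str]:
    if isinstance(genotypes, (int, np.integer)):
        return [f"G{i + 1:02d}" for i in range(int(genotypes))]
    labels = [str(g) for g in genotypes]
    if len(set(labels)) != len(labels):
        raise ValueError("genotype labels must be unique")
    return labels


def draw_mixtures(
    genotype_ids: list[str],
    mixtures_per_genotype: int,
    rng: np.random.Generator,
    max_retries: int = 5000,
) -> list[tuple[str, str]]:
    """Draw unordered, distinct genotype pairs with an exact per-genotype quota.

    Uses a seeded configuration-model construction: a stub list with each
    genotype repeated ``mixtures_per_genotype`` times is shuffled and paired
    consecutively; draws with self-pairs or duplicate pairs are rejected and
    redrawn (bounded retries).
    """
    n, q = len(genotype_ids), mixtures_per_genotype
    if q < 1:
        raise ValueError("mixtures_per_genotype must be >= 1")
    if (n * q) % 2 != 0:
        raise ValueError(
            f"cannot form mixtures: {n} genotypes x quota {q} gives an odd "
            f"number of mixture slots ({n * q}); the product must be even"
        )
    if q > n - 1:
        raise ValueError(
            f"quota {q} exceeds the {n - 1} distinct partners available per genotype"
        )
    idx = np.repeat(np.arange(n), q)
    for _ in range(max_retries):
        perm = rng.permutation(idx)
        pairs = np.sort(perm.reshape(-1, 2), axis=1)
        if np.any(pairs[:, 0] == pairs[:, 1]):
            continue
        as_tuples = [tuple(p) for p in pairs]
        if len(set(as_tuples)) != len(as_tuples):
            continue
        as_tuples.sort()
        return [(genotype_ids[i], genotype_ids[j]) for i, j in as_tuples]
    raise RuntimeError(
        f"no valid mixture assignment found in {max_retries} retries; "
        "the pairing constraints may be infeasible"
    )


def generate_design(
    genotypes,
    mixtures_per_genotype: int = 3,
    n_blocks: int = 3,
    treatments: tuple[str, ...] = ("R+", "R-"),
    n_dates: int = 4,
    controls_per_block_per_treatment: int = 6,
    seed: int | np.random.Generator = 0,
    control_genotype: str = CONTROL_GENOTYPE,
) -> pd.DataFrame:
    """Generate the pot-level experimental layout.

    Parameters
    ----------
    genotypes
        Number of genotypes (labels are generated) or a sequence of labels.
    mixtures_per_genotype
        How many distinct binary mixtures each genotype appears in.
    treatments
        Treatment labels; every pure stand and mixture is replicated in every
        block of every treatment.
    n_dates
        Number of consecutive harvest dates; pots within each
        block x treatment are split evenly across them.

    Returns
    -------
    DataFrame with one row per pot: tube_id, treatment, block, harvest_date,
    is_control, is_mixture and the per-position genotype columns pos1..pos6.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = _genotype_labels(genotypes)
    if control_genotype in labels:
        raise ValueError("control genotype label collides with a panel genotype")
    mixtures = draw_mixtures(labels, mixtures_per_genotype, rng)

    rows = []
    for treatment in treatments:
        for block in range(1, n_blocks + 1):
            compositions: list[tuple[list[str], bool, bool]] = []
            for g in labels:
                compositions.append(([g] * PLANTS_PER_POT, False, False))
            for a, b in mixtures:
                compositions.append(([a, b] * (PLANTS_PER_POT // 2), False, True))
            for _ in range(controls_per_block_per_treatment):
                compositions.append(([control_genotype] * PLANTS_PER_POT, True, False))
            order = rng.permutation(len(compositions))
            for slot, k in enumerate(order):
                comp, is_control, is_mixture = compositions[k]
                rows.append(
                    {
                        "treatment": treatment,
                        "block": block,
                        "harvest_date": slot % n_dates + 1,
                        "is_control": is_control,
                        "is_mixture": is_mixture,
                        **{f"pos{i + 1}": g for i, g in enumerate(comp)},
                    }
                )
    design = pd.DataFrame(rows)
    design.insert(0, "tube_id", [f"T{i + 1:04d}" for i in range(len(design))])
    return design[DESIGN_COLUMNS]


def design_composition(design: pd.DataFrame) -> pd.DataFrame:
    """Per-pot genotype composition: distinct genotypes and plant counts."""
    pos_cols = [c for c in design.columns if c.startswith("pos")]
    out = []
    for _, row in design.iterrows():
        comp = [row[c] for c in pos_cols]
        distinct = sorted(set(comp))
        out.append(
            {
                "tube_id": row["tube_id"],
                "genotypes": tuple(distinct),
                "n_distinct": len(distinct),
            }
        )
    return pd.DataFrame(out)


def mixture_pairs(design: pd.DataFrame) -> list[tuple[str, str]]:
    """The distinct unordered genotype pairs among non-control mixture pots."""
    pos_cols = [c for c in design.columns if c.startswith("pos")]
    mixed = design[design["is_mixture"] & ~design["is_control"]]
    pairs = set()
    for _, row in mixed.iterrows():
        distinct = tuple(sorted(set(row[c] for c in pos_cols)))
        if len(distinct) != 2:
            raise ValueError(f"mixture pot {row['tube_id']} has {len(distinct)} genotypes")
        pairs.add(distinct)
    return sorted(pairs)
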