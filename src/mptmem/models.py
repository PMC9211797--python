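"""Built-in recognition-memory models, study fixtures, and frequency I/O.

Two MPT models of recognition memory are provided, each duplicated over
an animacy factor (animate vs. inanimate words):

* the **four-states model** for the remember-know-guess paradigm, which
  decomposes "detailed recollection", "feeling of familiarity",
  "guessing", and "new" judgments into recollection (r), conditional
  familiarity (f), detection of new words (d), and a cascade of guessing
  parameters (g_r, g_f, g_g) shared between the old-word and new-word
  trees of a set;

* the **two-high-threshold process-dissociation model**, which decomposes
  "old"/"new" judgments under inclusion and exclusion instructions into
  recollection (r), conditional familiarity (f), new-word detection (d),
  and instruction-specific guessing (g_i, g_e).

The module also reconstructs the aggregate frequency tables of the two
animacy experiments from their published mean proportions and totals
(110 participants x 40 items per cell for the remember-know-guess study;
81 x 26 inclusion and 82 x 26 exclusion responses per cell for the
process-dissociation study), using largest-remainder rounding so each
tree's counts sum exactly to its total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Branch,
    BranchTerm,
    Equate,
    FrequencyTable,
    MPTModel,
    ParamSpec,
    Restriction,
    Tree,
)

__all__ = [
    "ExperimentFixture",
    "build_four_states",
    "build_pd_two_ht",
    "reconstruct_counts",
    "fixture_experiment1",
    "fixture_experiment2",
    "read_frequency_csv",
    "write_frequency_csv",
    "TABLE2_PROPORTIONS",
    "TABLE5_PROPORTIONS",
]

ANIMACY = ("animate", "inanimate")


@dataclass(frozen=True)
class ExperimentFixture:
    """A built-in model with its restriction ladder and frequency data."""

    name: str
    model: MPTModel
    base_restrictions: tuple[Restriction, ...]
    hypotheses: dict[str, tuple[Restriction, ...]]
    data: FrequencyTable
    n_total: int

    def __post_init__(self) -> None:
        self.data.validate_against(self.model)
        assert self.n_total == self.data.total


# --------------------------------------------------------------------------
# Four-states model (remember-know-guess paradigm)
# --------------------------------------------------------------------------

def _four_states_trees(suffix: str) -> tuple[list[Tree], list[Branch]]:
    r, f, d = f"r_{suffix}", f"f_{suffix}", f"d_{suffix}"
    gr, gf, gg = f"gr_{suffix}", f"gf_{suffix}", f"gg_{suffix}"
    cats = ("recollection", "familiarity", "guessing", "new")
    old, new = f"old_{suffix}", f"new_{suffix}"

    def T(p: str) -> BranchTerm:
        return BranchTerm(p)

    def C(p: str) -> BranchTerm:
        return BranchTerm(p, complement=True)

    # uncertainty-state guessing cascade, shared between old and new trees
    guess = [
        ("recollection", (T(gr),)),
        ("familiarity", (C(gr), T(gf))),
        ("guessing", (C(gr), C(gf), T(gg))),
        ("new", (C(gr), C(gf), C(gg))),
    ]
    trees = [
        Tree(old, cats, item_type=f"old-{suffix}"),
        Tree(new, cats, item_type=f"new-{suffix}"),
    ]
    branches = [
        Branch(old, "recollection", (T(r),)),
        Branch(old, "familiarity", (C(r), T(f))),
    ]
    branches += [
        Branch(old, cat, (C(r), C(f)) + terms) for cat, terms in guess
    ]
    branches.append(Branch(new, "new", (T(d),)))
    branches += [Branch(new, cat, (C(d),) + terms) for cat, terms in guess]
    return trees, branches


def build_four_states() -> tuple[MPTModel, dict[str, tuple[Restriction, ...]]]:
    """The four-states model duplicated over animacy, with its hypothesis
    restriction sets.

    Returns the 12-parameter model (r, f, d, g_r, g_f, g_g per animacy
    set) and the named restriction sets: ``BASE_G`` equates each guessing
    parameter across animacy (the base model of the analysis); ``H_R``,
    ``H_F`` and ``H_D`` additionally equate recollection, familiarity or
    new-word detection across animacy, respectively.
    """
    descriptions = {
        "r": "probability of recollection",
        "f": "conditional probability of familiarity given no recollection",
        "d": "probability of detecting a new word as new",
        "gr": "conditional probability of guessing 'detailed recollection'",
        "gf": "conditional probability of guessing 'feeling of familiarity'",
        "gg": "conditional probability of choosing 'guessing'",
    }
    params, trees, branches = [], [], []
    for suffix in ANIMACY:
        for base, desc in descriptions.items():
            params.append(ParamSpec(f"{base}_{suffix}", f"{desc} ({suffix})"))
        t, b = _four_states_trees(suffix)
        trees += t
        branches += b
    model = MPTModel(tuple(params), tuple(trees), tuple(branches),
                     name="four_states")
    restrictions = {
        "BASE_G": tuple(Equate(f"{g}_animate", f"{g}_inanimate")
                        for g in ("gr", "gf", "gg")),
        "H_R": (Equate("r_animate", "r_inanimate"),),
        "H_F": (Equate("f_animate", "f_inanimate"),),
        "H_D": (Equate("d_animate", "d_inanimate"),),
    }
    return model, restrictions


# --------------------------------------------------------------------------
# Two-high-threshold process-dissociation model
# --------------------------------------------------------------------------

def build_pd_two_ht() -> tuple[MPTModel, dict[str, tuple[Restriction, ...]]]:
    """The two-high-threshold process-dissociation model duplicated over
    animacy.

    Eight binomial trees (inclusion/exclusion x old-Phase-1/new x
    animacy) over the parameters r, f, d, g_i, g_e per animacy set.
    Restriction sets: ``RD_ALIAS`` equates recollection with new-word
    detection within each animacy set (without it the 10-parameter model
    is not identifiable from the 8 independent data cells); ``BASE_G``
    equates each guessing parameter across animacy; ``H_R`` and ``H_F``
    equate recollection / familiarity across animacy.
    """
    params, trees, branches = [], [], []
    for suffix in ANIMACY:
        r, f, d = f"r_{suffix}", f"f_{suffix}", f"d_{suffix}"
        gi, ge = f"gi_{suffix}", f"ge_{suffix}"
        params += [
            ParamSpec(r, f"probability of recollection ({suffix})"),
            ParamSpec(f, f"conditional familiarity given no recollection ({suffix})"),
            ParamSpec(d, f"probability of detecting a new word as new ({suffix})"),
            ParamSpec(gi, f"probability of guessing 'old' under inclusion ({suffix})"),
            ParamSpec(ge, f"probability of guessing 'old' under exclusion ({suffix})"),
        ]
        cats = ("old", "new")

        def T(p: str) -> BranchTerm:
            return BranchTerm(p)

        def C(p: str) -> BranchTerm:
            return BranchTerm(p, complement=True)

        inc_old = f"inclusion_old_{suffix}"
        exc_old = f"exclusion_old_{suffix}"
        inc_new = f"inclusion_new_{suffix}"
        exc_new = f"exclusion_new_{suffix}"
        trees += [
            Tree(inc_old, cats, item_type=f"inclusion-old-{suffix}"),
            Tree(exc_old, cats, item_type=f"exclusion-old-{suffix}"),
            Tree(inc_new, cats, item_type=f"inclusion-new-{suffix}"),
            Tree(exc_new, cats, item_type=f"exclusion-new-{suffix}"),
        ]
        branches += [
            # inclusion, Phase-1 word: recollection or familiarity or guess
            Branch(inc_old, "old", (T(r),)),
            Branch(inc_old, "old", (C(r), T(f))),
            Branch(inc_old, "old", (C(r), C(f), T(gi))),
            Branch(inc_old, "new", (C(r), C(f), C(gi))),
            # exclusion, Phase-1 word: recollection leads to (correct) "new"
            Branch(exc_old, "new", (T(r),)),
            Branch(exc_old, "old", (C(r), T(f))),
            Branch(exc_old, "old", (C(r), C(f), T(ge))),
            Branch(exc_old, "new", (C(r), C(f), C(ge))),
            # new words: detection or guessing
            Branch(inc_new, "new", (T(d),)),
            Branch(inc_new, "old", (C(d), T(gi))),
            Branch(inc_new, "new", (C(d), C(gi))),
            Branch(exc_new, "new", (T(d),)),
            Branch(exc_new, "old", (C(d), T(ge))),
            Branch(exc_new, "new", (C(d), C(ge))),
        ]
    model = MPTModel(tuple(params), tuple(trees), tuple(branches),
                     name="pd_two_ht")
    restrictions = {
        "RD_ALIAS": (Equate("r_animate", "d_animate"),
                     Equate("r_inanimate", "d_inanimate")),
        "BASE_G": (Equate("gi_animate", "gi_inanimate"),
                   Equate("ge_animate", "ge_inanimate")),
        "H_R": (Equate("r_animate", "r_inanimate"),),
        "H_F": (Equate("f_animate", "f_inanimate"),),
    }
    return model, restrictions


# --------------------------------------------------------------------------
# Reconstructing counts from published proportions
# --------------------------------------------------------------------------

def reconstruct_counts(proportions: Sequence[float], total: int) -> list[int]:
    """Integer counts from rounded proportions by largest-remainder
    rounding.

    The proportions are rescaled to sum to one (published rows round to
    sums of 0.99-1.01), multiplied by the total, floored, and the
    remaining units assigned to the cells with the largest fractional
    parts (ties broken by position).  The result always sums exactly to
    ``total``.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0):
        raise ValueError("proportions must be nonnegative")
    s = props.sum()
    if s <= 0:
        raise ValueError("proportions must not be all zero")
    if total <= 0:
        raise ValueError("total must be positive")
    exact = props / s * total
    floors = np.floor(exact).astype(int)
    remainder = int(total - floors.sum())
    frac = exact - floors
    # stable sort => ties go to the earlier category
    order = np.argsort(-frac, kind="stable")
    for i in order[:remainder]:
        floors[i] += 1
    return floors.tolist()


# Published mean proportions of the two studies (rows: tree; columns in
# the tree's category order).
TABLE2_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "old_animate": (0.53, 0.23, 0.06, 0.19),
    "old_inanimate": (0.48, 0.25, 0.07, 0.20),
    "new_animate": (0.02, 0.07, 0.05, 0.86),
    "new_inanimate": (0.03, 0.09, 0.06, 0.82),
}

TABLE5_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "inclusion_old_animate": (0.84, 0.16),
    "inclusion_old_inanimate": (0.80, 0.20),
    "inclusion_new_animate": (0.15, 0.85),
    "inclusion_new_inanimate": (0.16, 0.84),
    "exclusion_old_animate": (0.28, 0.72),
    "exclusion_old_inanimate": (0.30, 0.70),
    "exclusion_new_animate": (0.12, 0.88),
    "exclusion_new_inanimate": (0.13, 0.87),
}

#: responses per tree: 110 participants x 40 items of each type
EXP1_TREE_TOTAL = 110 * 40
#: responses per tree: 81 (inclusion) / 82 (exclusion) participants x 26 items
EXP2_INCLUSION_TOTAL = 81 * 26
EXP2_EXCLUSION_TOTAL = 82 * 26


def _counts_from_proportions(
    model: MPTModel, proportions: Mapping[str, Sequence[float]],
    totals: Mapping[str, int],
) -> FrequencyTable:
    counts: dict[tuple[str, str], int] = {}
    for tree in model.trees:
        row = reconstruct_counts(proportions[tree.name], totals[tree.name])
        for cat, n in zip(tree.categories, row):
            counts[(tree.name, cat)] = n
    return FrequencyTable(counts)


def fixture_experiment1() -> ExperimentFixture:
    """Remember-know-guess study: four-states model plus the aggregate
    frequency table reconstructed from the published judgment proportions
    (4400 responses per tree, 17,600 in total)."""
    model, restr = build_four_states()
    totals = {t.name: EXP1_TREE_TOTAL for t in model.trees}
    data = _counts_from_proportions(model, TABLE2_PROPORTIONS, totals)
    return ExperimentFixture(
        name="exp1",
        model=model,
        base_restrictions=restr["BASE_G"],
        hypotheses={k: restr[k] for k in ("H_R", "H_F", "H_D")},
        data=data,
        n_total=data.total,
    )


def fixture_experiment2() -> ExperimentFixture:
    """Process-dissociation study: two-high-threshold model plus counts
    reconstructed from the published "old"/"new" proportions (2106
    responses per inclusion tree, 2132 per exclusion tree, 16,952 in
    total).  The base restrictions combine the r=d identification aliases
    with the guessing equates."""
    model, restr = build_pd_two_ht()
    totals = {
        t.name: (EXP2_INCLUSION_TOTAL if t.name.startswith("inclusion")
                 else EXP2_EXCLUSION_TOTAL)
        for t in model.trees
    }
    data = _counts_from_proportions(model, TABLE5_PROPORTIONS, totals)
    return ExperimentFixture(
        name="exp2",
        model=model,
        base_restrictions=restr["RD_ALIAS"] + restr["BASE_G"],
        hypotheses={k: restr[k] for k in ("H_R", "H_F")},
        data=data,
        n_total=data.total,
    )


# --------------------------------------------------------------------------
# Frequency CSV I/O
# --------------------------------------------------------------------------

def read_frequency_csv(path: str | Path) -> FrequencyTable:
    """Read a frequency table from a CSV with columns tree, category,
    count."""
    df = pd.read_csv(path, dtype={"tree": str, "category": str})
    missing = {"tree", "category", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"frequency CSV missing columns: {sorted(missing)}")
    counts: dict[tuple[str, str], int] = {}
    triples = zip(df["tree"], df["category"], df["count"])
    for i, (tree, cat, n) in enumerate(triples, start=2):
        if pd.isna(n) or float(n) != int(n) or int(n) < 0:
            raise ValueError(f"row {i}: count must be a nonnegative integer, got {n!r}")
        key = (tree, cat)
        if key in counts:
            raise ValueError(f"row {i}: duplicate cell {key!r}")
        counts[key] = int(n)
    return FrequencyTable(counts)


def write_frequency_csv(table: FrequencyTable, path: str | Path) -> None:
    """Write a frequency table as CSV, rows ordered by tree then category."""
    rows = sorted(table.counts.items())
    df = pd.DataFrame(
        [(t, c, n) for (t, c), n in rows],
        columns=["tree", "category", "count"],
    )
    df.to_csv(path, index=False)
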