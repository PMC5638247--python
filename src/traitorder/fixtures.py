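"""Seeded example datasets: the warbler quartet, simulator outputs, a supertree.

These are generated, never shipped: every fixture is a deterministic function
of its seed, so tests and demos rebuild them on the fly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .null import DisplacementConfig, SimConfig, simulate_bm, simulate_displacement, simulate_yule, tip_table
from .traits import TraitTable
from .tree import Tree, Node, parse_newick, write_newick

__all__ = [
    "QUARTET_NEWICK",
    "QUARTET_ROTATED_NEWICK",
    "QUARTET_RANKS",
    "quartet_tree",
    "quartet_traits",
    "three_taxon_tree",
    "screening_supertree",
    "generate_fixtures",
]

#: the four-warbler worked example: tip order and body-mass ranks chosen so the
#: as-written orientation gives tau = 2/3 and the double-cherry rotation tau = 0
QUARTET_NEWICK = "((virens,chrysoparia),(townsendii,occidentalis));"
QUARTET_ROTATED_NEWICK = "((chrysoparia,virens),(occidentalis,townsendii));"
QUARTET_RANKS = {"virens": 1.0, "townsendii": 2.0, "chrysoparia": 3.0, "occidentalis": 4.0}

#: the same topology with plausible ultrametric branch lengths, for operations
#: that need time (BM simulation, gamma); times are arbitrary units
QUARTET_NEWICK_DATED = (
    "((virens:1,chrysoparia:1):1,(townsendii:1,occidentalis:1):1);"
)

THREE_TAXON_NEWICK = "(virens,(townsendii,occidentalis));"


def quartet_tree(dated: bool = False) -> Tree:
    return parse_newick(QUARTET_NEWICK_DATED if dated else QUARTET_NEWICK)


def quartet_traits() -> TraitTable:
    return TraitTable(QUARTET_RANKS)


def three_taxon_tree() -> Tree:
    return parse_newick(THREE_TAXON_NEWICK)


def _comb_tree(join_ages: list[float], prefix: str) -> Tree:
    """Pectinate ultrametric tree: clade of k tips has crown age join_ages[k-2]."""
    ages = sorted(join_ages)
    total = ages[-1]
    clade = Node(label=f"{prefix}_t1", length=ages[0])
    sibling = Node(label=f"{prefix}_t2", length=ages[0])
    clade = Node(children=[clade, sibling])
    for i, age in enumerate(ages[1:], start=3):
        clade.length = age - ages[i - 3]
        new_tip = Node(label=f"{prefix}_t{i}", length=age)
        clade = Node(children=[clade, new_tip])
    clade.length = None
    tree = Tree(clade)
    # tips joined at age a sit at depth total - ... equalize to the crown age
    depths = tree.depths()
    crown = max(depths.values())
    for tip in tree.tips:
        tip.length += crown - depths[tip.id]
    return Tree(clade)


def screening_supertree(seed: int = 0) -> tuple[Tree, TraitTable]:
    """A supertree in which exactly three clades pass the default screen.

    Three 12-tip Yule clades of crown age 10 with full trait coverage hang
    from a 30-unit backbone.  Two decoys fail exactly one criterion each: a
    12-tip age-10 clade with only 7 of 12 species measured (coverage 58%),
    and a 14-tip pectinate clade of crown age 25 whose every >=10-tip
    subclade is older than 15 (so neither it nor anything inside it passes
    the age cap).  Every backbone ancestor is older than 15, so the three
    qualifying clades are maximal and unique.
    """
    rng = np.random.default_rng(seed)
    clades: list[Tree] = []
    for i in range(4):
        t = simulate_yule(12, seed=int(rng.integers(2**31)), crown_age=10.0)
        for tip in t.tips:
            tip.label = f"c{i + 1}_{tip.label}"
        clades.append(t)
    # old comb clade: k-tip subclades (k >= 10) all older than the 15-unit cap
    comb_ages = [2.0 + 23.0 * k / 12.0 for k in range(13)]  # ages 2 .. 25; 10-tip age 17.3
    clades.append(_comb_tree(comb_ages, "c5"))

    def stem(tree: Tree, parent_depth: float, clade_root_depth: float) -> Node:
        root = Tree._clone(tree.root)
        root.length = clade_root_depth - parent_depth
        return root

    # depths: tips at 30; c1-c4 roots at 20, comb root at 5
    n12 = Node(length=None, children=[stem(clades[0], 12.0, 20.0), stem(clades[1], 12.0, 20.0)])
    n12.length = 4.0   # depth 12, crown age 18
    n8 = Node(length=3.0, children=[n12, stem(clades[2], 8.0, 20.0)])   # depth 8, age 22
    n5 = Node(length=3.0, children=[n8, stem(clades[4], 5.0, 5.0 + 1e-9)])  # depth 5, age 25
    n2 = Node(length=2.0, children=[n5, stem(clades[3], 2.0, 20.0)])    # depth 2, age 28
    root = Node(children=[n2, Node(label="outgroup", length=30.0)])
    tree = Tree(root)

    values = {}
    for tip in tree.tips:
        values[tip.label] = float(rng.normal())
    # knock coverage of clade 4 below 80% (7 of 12 measured)
    for lbl in sorted(v for v in values if v.startswith("c4_"))[:5]:
        del values[lbl]
    traits = TraitTable(values)
    return tree, traits


def generate_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the fixture bundle; returns paths keyed by fixture name.

    Contents: the quartet worked example (topology exactly as printed, plus a
    dated version and the rank table), a 25-tip Yule tree with BM traits, a
    strict-displacement (p_c = 0) dataset on the same tree, and the screening
    supertree with its trait table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        paths[name] = p

    def write_traits(name: str, table: TraitTable) -> None:
        rows = "".join(f"{s}\t{table[s]:.10g}\n" for s in table.species)
        write(name, "species\tvalue\n" + rows)

    write("quartet.nwk", QUARTET_NEWICK + "\n")
    write("quartet_dated.nwk", QUARTET_NEWICK_DATED + "\n")
    write_traits("quartet_ranks.tsv", quartet_traits())

    yule = simulate_yule(25, seed=seed + 1)
    write("yule25.nwk", write_newick(yule) + "\n")
    bm_values = simulate_bm(yule, SimConfig(seed=seed + 2))
    write_traits("yule25_bm.tsv", tip_table(yule, bm_values))

    disp = simulate_displacement(yule, DisplacementConfig(p_c=0.0, seed=seed + 3))
    write_traits("yule25_displacement.tsv", disp)

    supertree, straits = screening_supertree(seed + 4)
    write("supertree.nwk", write_newick(supertree) + "\n")
    write_traits("supertree_mass.tsv", straits)
    return paths
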