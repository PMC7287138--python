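"""Synthetic study systems: trees, codon alignments, toy plastome records.

The generator emulates the fern rps12 setting end to end: an ultrametric
fern-like tree (root at 354 My) with designated intron-less (type II)
clades, a codon alignment evolved under branch-class MG94xHKY85 with an
optional rate multiplier on the inverted-repeat (IR) codons, and toy
plastome-like records in which exon 1 (38 codons, 114 nt) sits in an LSC
context while exons 2-3 are embedded twice as exact reverse complements
(the IR copies); type-I taxa carry a spacer (intron II) between exons 2 and
3, type-II taxa do not.

Defaults mirror the study gene: 372-bp CDS = 123 amino acids + stop, 38 SC
codons + 85 IR codons; omega 0.1 and kappa 2 for both branch classes
(a conserved ribosomal protein); strict clock with an optional lognormal
relaxation.  Everything is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .gene_model import (
    CodonAlignment,
    ExonRecord,
    GeneModel,
    write_annotation_table,
)
from .phylo import Node, Tree
from .subst_models import (
    CODONS,
    MG94Params,
    mg94_matrix,
)

__all__ = ["SimConfig", "SyntheticBundle", "SimConfigError",
           "simulate_tree", "simulate_codon_alignment",
           "emit_plastome_records", "simulate_bundle"]

# AT-rich plastid-like positional nucleotide frequencies (A, C, G, T)
DEFAULT_POS_FREQS = np.array(
    [
        [0.29, 0.17, 0.23, 0.31],
        [0.28, 0.20, 0.18, 0.34],
        [0.32, 0.15, 0.17, 0.36],
    ]
)

STOP_APPENDED = "TAA"


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_taxa: int = 16
    n_codons: int = 124  # CDS codons including the terminal stop
    tree_shape: str = "birth-death"  # birth-death | balanced | ladder
    typeII_clades: list[int] = field(default_factory=lambda: [3, 2])
    omega_by_class: dict = field(
        default_factory=lambda: {"typeI": 0.1, "typeII": 0.1}
    )
    kappa_by_class: dict = field(
        default_factory=lambda: {"typeI": 2.0, "typeII": 2.0}
    )
    region_effect: float = 1.0  # multiplier on IR-codon branch lengths
    rate_by_class: dict = field(
        default_factory=lambda: {"typeI": 1.0, "typeII": 1.0}
    )  # absolute-rate multiplier per branch class (plants an R_S/R_N shift)
    clock: str = "strict"  # strict | lognormal
    clock_sigma: float = 0.3
    root_age: float = 354.0  # My (fern crown-group calibration)
    mean_rate: float = 5e-4  # substitutions/site/My
    sc_codons: int = 38  # SC/IR split (codons 1..38 = SC)
    standard_layout: bool = True  # rps12-style records with appended stop
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.omega_by_class.values()):
            raise SimConfigError("omega values must be > 0")
        if any(v <= 0 for v in self.kappa_by_class.values()):
            raise SimConfigError("kappa values must be > 0")
        if self.region_effect <= 0 or self.mean_rate <= 0:
            raise SimConfigError("rates and multipliers must be > 0")
        if sum(self.typeII_clades) >= self.n_taxa:
            raise SimConfigError("typeII clade sizes must sum to < n_taxa")
        if self.standard_layout and self.n_codons < self.sc_codons + 1:
            raise SimConfigError(
                "n_codons too small for the requested SC/IR split"
            )

    @property
    def n_sense_codons(self) -> int:
        return self.n_codons - 1 if self.standard_layout else self.n_codons

    def partition(self) -> list[str]:
        """Per sense codon: SC for codons 1..sc_codons, IR beyond."""
        return ["SC"] * self.sc_codons + ["IR"] * (
            self.n_sense_codons - self.sc_codons
        )


@dataclass
class SyntheticBundle:
    config: SimConfig
    tree: Tree  # ages, branch classes, true subs/site lengths
    alignment: CodonAlignment  # sense codons, partitioned
    protein_alignment: dict
    gene_models: list[GeneModel]
    records: dict  # taxon -> toy plastome-like sequence
    truth: "np.ndarray | object"  # pandas DataFrame of per-branch truth


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------


def simulate_tree(config: SimConfig) -> Tree:
    """Ultrametric tree with root at ``config.root_age`` and the requested
    type-II clades labeled (stem branches included)."""
    shape = config.tree_shape
    if shape == "balanced":
        tree = _balanced_tree(config.n_taxa, config.root_age)
        _label_typeII(tree, config.typeII_clades)
    elif shape == "ladder":
        tree = _ladder_tree(config.n_taxa, config.root_age)
        _label_typeII(tree, config.typeII_clades)
    elif shape == "birth-death":
        tree = None
        for attempt in range(50):
            cand = _birth_death_tree(
                config.n_taxa, config.root_age, config.seed + 1000 * attempt
            )
            try:
                _label_typeII(cand, config.typeII_clades)
            except SimConfigError:
                continue
            tree = cand
            break
        if tree is None:
            raise SimConfigError(
                f"no tree with disjoint clades of sizes {config.typeII_clades} "
                f"found in 50 draws"
            )
    else:
        raise SimConfigError(f"unknown tree shape {shape!r}")
    tree.reindex()
    return tree


def _balanced_tree(n_taxa: int, root_age: float) -> Tree:
    depth = int(np.log2(n_taxa))
    if 2**depth != n_taxa:
        raise SimConfigError("balanced shape requires n_taxa a power of 2")
    counter = iter(range(1, n_taxa + 1))

    def build(level: int) -> Node:
        node = Node()
        node.age = root_age * (0.5**level)
        if level == depth:
            node.name = f"t{next(counter)}"
            node.age = 0.0
            return node
        node.add_child(build(level + 1))
        node.add_child(build(level + 1))
        return node

    root = build(0)
    tree = Tree(root)
    tree.set_lengths_from_ages()
    return tree


def _ladder_tree(n_taxa: int, root_age: float) -> Tree:
    ages = np.linspace(root_age, root_age / (n_taxa - 1), n_taxa - 1)
    root = Node()
    root.age = ages[0]
    node = root
    for k in range(n_taxa - 1):
        tip = Node(name=f"t{k + 1}")
        tip.age = 0.0
        node.add_child(tip)
        if k < n_taxa - 2:
            inner = Node()
            inner.age = ages[k + 1]
            node.add_child(inner)
            node = inner
        else:
            last = Node(name=f"t{n_taxa}")
            last.age = 0.0
            node.add_child(last)
    tree = Tree(root)
    tree.set_lengths_from_ages()
    return tree


def _birth_death_tree(n_taxa: int, root_age: float, seed: int) -> Tree:
    from dendropy.simulate import treesim

    dt = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    tree = Tree.from_newick(dt.as_string(schema="newick"))
    # the last speciation leaves zero-length terminal branches; pad all tips
    tree.set_ages_from_lengths()
    height = tree.root.age
    pad = 0.05 * height if height > 0 else 1.0
    for node in tree.postorder():
        node.age = node.age + pad if not node.is_leaf else 0.0
        if node.is_leaf:
            node.length += pad
    scale = root_age / tree.root.age
    for node in tree.postorder():
        node.age *= scale
    tree.set_lengths_from_ages()
    return tree


def _label_typeII(tree: Tree, clade_sizes: list[int]) -> None:
    """Mark disjoint clades of the requested sizes as typeII (with stems)."""
    for node in tree.postorder():
        node.klass = "typeI"
    taken: set[int] = set()
    sizes = {}
    for node in tree.postorder():
        sizes[id(node)] = (
            1 if node.is_leaf else sum(sizes[id(c)] for c in node.children)
        )
    for want in sorted(clade_sizes, reverse=True):
        found = None
        for node in tree.postorder():
            if node.is_root or sizes[id(node)] != want:
                continue
            subtree = list(_descendants(node))
            if any(id(d) in taken for d in subtree):
                continue
            found = node
            break
        if found is None:
            raise SimConfigError(
                f"no unused clade of size {want} in the simulated topology"
            )
        for d in _descendants(found):
            d.klass = "typeII"
            taken.add(id(d))


def _descendants(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def tip_type_map(tree: Tree) -> dict[str, str]:
    return {
        n.name: ("II" if n.klass == "typeII" else "I") for n in tree.leaves()
    }


# --------------------------------------------------------------------------
# sequence simulation
# --------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: Tree, config: SimConfig, rng: Optional[np.random.Generator] = None
):
    """Evolve sense codons along the tree under branch-class MG94xHKY85.

    Sets each branch's ``length`` to its realized expected substitutions per
    site (clock rate x duration x lognormal multiplier); IR codons evolve
    with the branch length scaled by ``config.region_effect``.  Returns
    (alignment, truth DataFrame).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    classes = sorted(set(config.omega_by_class))
    params = {
        c: MG94Params(
            kappa=config.kappa_by_class[c],
            omega_by_class={c: config.omega_by_class[c]},
            pos_freqs=DEFAULT_POS_FREQS,
        )
        for c in classes
    }
    matrices = {c: mg94_matrix(params[c], c) for c in classes}
    pi = matrices[classes[0]].pi
    nsense = config.n_sense_codons
    part = np.array(config.partition())
    is_ir = part == "IR"

    # branch substitution lengths
    for node in tree.branches():
        dt = node.parent.age - node.age
        mult = 1.0
        if config.clock == "lognormal":
            s = config.clock_sigma
            mult = float(np.exp(rng.normal(-0.5 * s * s, s)))
        elif config.clock != "strict":
            raise SimConfigError(f"unknown clock model {config.clock!r}")
        mult *= config.rate_by_class.get(node.klass, 1.0)
        node.rate = config.mean_rate * mult
        node.length = node.rate * dt

    states = {id(tree.root): rng.choice(len(CODONS), size=nsense, p=pi)}
    for node in tree.preorder():
        if node.is_root:
            continue
        parent_states = states[id(node.parent)]
        klass = node.klass or classes[0]
        rm = matrices[klass if klass in matrices else classes[0]]
        out = np.empty(nsense, dtype=np.int64)
        for ir_flag in (False, True):
            mask = is_ir == ir_flag
            if not mask.any():
                continue
            t = node.length * (config.region_effect if ir_flag else 1.0)
            P = rm.transition_probs(t)
            sub = parent_states[mask]
            drawn = np.empty(len(sub), dtype=np.int64)
            for s in np.unique(sub):
                sel = sub == s
                drawn[sel] = rng.choice(len(CODONS), size=sel.sum(), p=P[s])
            out[mask] = drawn
        states[id(node)] = out

    taxa = sorted(tree.leaf_names())
    leaf_by_name = {n.name: n for n in tree.leaves()}
    rows = [
        [CODONS[s] for s in states[id(leaf_by_name[t])]] for t in taxa
    ]
    aln = CodonAlignment(taxa, rows, list(part))

    truth_rows = []
    for node in tree.branches():
        truth_rows.append(
            dict(
                clade="|".join(sorted(tree.clade_key(node))),
                branch_class=node.klass,
                dt_my=node.parent.age - node.age,
                rate=node.rate,
                subs_per_site=node.length,
            )
        )
    truth = pd.DataFrame(truth_rows)
    return aln, truth


def protein_alignment_of(aln: CodonAlignment) -> dict[str, str]:
    from .subst_models import GENETIC_CODE

    return {
        t: "".join(GENETIC_CODE[c] for c in aln.row(t)) for t in aln.taxa
    }


# --------------------------------------------------------------------------
# toy plastome records
# --------------------------------------------------------------------------


def emit_plastome_records(
    aln: CodonAlignment,
    tree: Tree,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Embed each taxon's CDS in a toy plastome-like record.

    Layout per record: LSC flank / exon 1 / spacer / IR copy A (exon 2,
    intron-II spacer for type-I taxa, exon 3) / SSC spacer / IR copy B
    (exact reverse complement of copy A).  Returns (records, gene_models).
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    types = tip_type_map(tree)
    sc_nt = 3 * config.sc_codons
    records, models = {}, []
    for taxon in aln.taxa:
        cds = "".join(aln.row(taxon)) + (
            STOP_APPENDED if config.standard_layout else ""
        )
        exon1 = cds[:sc_nt]
        ir_cds = cds[sc_nt:]
        # exon2/exon3 split inside the IR block (codons 39..81 / 82..end+stop
        # in the standard layout; clamped for shorter toy genes)
        exon2_codons = max(1, min(43, len(ir_cds) // 3 - 1))
        exon2 = ir_cds[: 3 * exon2_codons]
        exon3 = ir_cds[3 * exon2_codons :]
        intron1_present = True  # intron I flanks exon 1 in the real gene
        is_type1 = types[taxon] == "I"
        flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        lsc_left, lsc_right = flank(120), flank(80)
        intron2 = flank(200) if is_type1 else ""
        ir_block = exon2 + intron2 + exon3
        ssc = flank(150)
        between = flank(60)
        record = (
            lsc_left
            + exon1
            + lsc_right
            + ir_block
            + ssc
            + str(Seq(ir_block).reverse_complement())
            + between
        )
        records[taxon] = record
        e1_start = len(lsc_left)
        irA = e1_start + len(exon1) + len(lsc_right)
        irB = irA + len(ir_block) + len(ssc)
        exons = [
            ExonRecord(taxon, 1, "LSC", e1_start, e1_start + len(exon1), "+", 1),
            ExonRecord(taxon, 2, "IR", irA, irA + len(exon2), "+", 1),
            ExonRecord(
                taxon,
                3,
                "IR",
                irA + len(exon2) + len(intron2),
                irA + len(ir_block),
                "+",
                1,
            ),
            # copy 2: reverse complement block; exon 3 comes first on + coords
            ExonRecord(
                taxon,
                3,
                "IR",
                irB,
                irB + len(exon3),
                "-",
                2,
            ),
            ExonRecord(
                taxon,
                2,
                "IR",
                irB + len(exon3) + len(intron2),
                irB + len(ir_block),
                "-",
                2,
            ),
        ]
        models.append(GeneModel(taxon, exons, intron2_present=is_type1))
    return records, models


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------


def simulate_bundle(config: SimConfig, outdir: Optional[str] = None) -> SyntheticBundle:
    """Generate a complete input bundle (and optionally write it to disk)."""
    import pandas as pd

    tree = simulate_tree(config)
    aln, truth = simulate_codon_alignment(tree, config)
    prot = protein_alignment_of(aln)
    records, models = emit_plastome_records(aln, tree, config)
    bundle = SyntheticBundle(config, tree, aln, prot, models, records, truth)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "records.fasta", records)
        _write_fasta(
            out / "cds.fasta",
            {
                t: "".join(aln.row(t))
                + (STOP_APPENDED if config.standard_layout else "")
                for t in aln.taxa
            },
        )
        _write_fasta(out / "proteins.fasta", prot)
        aln.write_fasta(str(out / "codon_alignment.fasta"))
        tree.write(str(out / "tree_true_phylogram.nwk"))
        tree.write(str(out / "tree_true_chronogram.nwk"),
                   length_of=lambda n: n.parent.age - n.age, ages=True)
        write_annotation_table(models, str(out / "annotations.tsv"))
        truth.to_csv(out / "truth_branches.tsv", sep="\t", index=False)
        types = tip_type_map(tree)
        pd.DataFrame(
            [{"taxon": t, "gene_type": types[t]} for t in sorted(types)]
        ).to_csv(out / "gene_types.tsv", sep="\t", index=False)
        cfg = asdict(config)
        with open(out / "config.txt", "w") as fh:
            for k in sorted(cfg):
                fh.write(f"{k}={cfg[k]}\n")
        pd.DataFrame(
            [{"codon": i + 1, "region": p} for i, p in enumerate(config.partition())]
        ).to_csv(out / "partition.tsv", sep="\t", index=False)
    return bundle


def _write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")
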