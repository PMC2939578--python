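"""Synthetic data with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here: a pure-birth
(Yule) phylogeny; a temperature trait evolved by Brownian motion along it;
proteomes whose expected amino-acid composition shifts linearly with
temperature (expected ERK = baseline + beta * (T - T_root), with mass moved
from the depleted letters D,N,Q,T,S,H,A to the enriched letters E,R,K);
coding sequences with a tunable third-position GC probability; diverged
ortholog families with known truth; similarity tables consistent with that
orthology; and two purpose-built panels — a confounded two-clade panel
(clade-level temperature and composition offsets that a naive correlation
sees but independent contrasts standardize away) and GC-confounded ortholog
pairs for exercising the codon-matched controls.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import phylo
from .composition import (
    AMINO_ACIDS,
    ERK_DEPLETED,
    ERK_ENRICHED,
    amino_acid_frequencies,
    erk_score,
)
from .composition import CODON_TO_AA
from .seqio import HIT_COLUMNS, CdsRecord, ProteinRecord

import pandas as pd

#: synonymous codons per amino acid, standard nuclear code
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)

_UNIFORM = {aa: 0.05 for aa in AMINO_ACIDS}


def default_frequencies() -> dict[str, float]:
    """Uniform baseline (0.05 per residue), baseline ERK = -20 pp."""
    return dict(_UNIFORM)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic panels.

    Defaults emulate a prokaryote-style panel: 50 species, temperatures
    spread by Brownian motion (sigma^2 = 100 degC^2 per unit branch on a
    unit-rate Yule tree gives tip spreads of a few tens of degC) clamped to
    the 0-103 degC range life occupies, and a composition-temperature slope
    beta of 0.05 percentage points of ERK per degC.
    """

    n_species: int = 50
    birth_rate: float = 1.0
    root_temperature: float = 50.0
    sigma2: float = 100.0
    clamp: tuple[float, float] | None = (0.0, 103.0)
    beta: float = 0.05
    baseline_frequencies: Mapping[str, float] = field(
        default_factory=default_frequencies
    )
    n_proteins: int = 100
    length_range: tuple[int, int] = (100, 300)
    gc3: float = 0.5
    substitution_rate: float = 0.1
    seed: int = 0


# -- tree and trait ----------------------------------------------------------


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> phylo.Phylogeny:
    """Ultrametric pure-birth tree with ``n_species`` leaves.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears the process runs for one more exponential waiting time so the
    final split does not sit at the present.  Deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("birth", "children", "label")

        def __init__(self, birth):
            self.birth = birth
            self.children = None
            self.label = None

    t = 0.0
    root = _N(0.0)
    active = [root]
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active[idx]
        node.children = (_N(t), _N(t))
        active[idx] = node.children[0]
        active.append(node.children[1])
    present = t + rng.exponential(1.0 / (birth_rate * n_species))
    for i, leaf in enumerate(active, start=1):
        leaf.label = f"s{i}"

    def nwk(node: _N, parent_birth: float) -> str:
        length = (node.children[0].birth if node.children else present) - node.birth
        if node.children:
            inner = ",".join(nwk(c, node.birth) for c in node.children)
            return f"({inner}):{length:.10f}"
        return f"{node.label}:{length:.10f}"

    # root edge length is reported as 0 by construction of nwk(root)
    text = nwk(root, 0.0).rsplit(":", 1)[0] + ";"
    return phylo.parse_newick(text)


def simulate_bm_trait(
    tree: phylo.Phylogeny,
    root_value: float = 50.0,
    sigma2: float = 100.0,
    seed: int = 0,
    clamp: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Brownian motion along the tree: each branch adds a Normal(0,
    sigma^2 * length) increment.  Optional clamping to a biological interval
    is applied to the leaf values only (it breaks exact BM, so leave it off
    for calibration runs)."""
    rng = np.random.default_rng(seed)
    values: dict = {tree.tree.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        step = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
        values[node] = values[node.parent_node] + step
        if node.is_leaf():
            v = values[node]
            if clamp is not None:
                v = min(max(v, clamp[0]), clamp[1])
            out[node.taxon.label] = v
    return out


# -- proteomes ---------------------------------------------------------------


def tilt_frequencies(
    base: Mapping[str, float], delta_erk_pp: float
) -> dict[str, float]:
    """Shift expected ERK by ``delta_erk_pp`` percentage points.

    Moves probability mass m = delta/200 from the depleted set to the
    enriched set, proportionally to the baseline frequencies within each
    set, leaving unscored letters untouched; the expected ERK of the tilted
    distribution is exactly baseline ERK + delta.
    """
    mass = delta_erk_pp / 200.0
    plus = sum(base[a] for a in ERK_ENRICHED)
    minus = sum(base[a] for a in ERK_DEPLETED)
    out = dict(base)
    for a in ERK_ENRICHED:
        out[a] = base[a] * (1 + mass / plus)
    for a in ERK_DEPLETED:
        out[a] = base[a] * (1 - mass / minus)
    if any(v < 0 for v in out.values()):
        raise ValueError(
            f"ERK tilt of {delta_erk_pp} pp drives a frequency negative; reduce beta or the temperature span"
        )
    return out


def expected_erk(freqs: Mapping[str, float]) -> float:
    """Analytic ERK of a frequency vector, in percentage points."""
    return 100.0 * (
        sum(freqs[a] for a in ERK_ENRICHED) - sum(freqs[a] for a in ERK_DEPLETED)
    )


def simulate_proteome(
    temperature: float,
    config: GeneratorConfig,
    seed: int = 0,
    species: str = "sp",
) -> tuple[list[ProteinRecord], float]:
    """i.i.d.-residue proteome whose expected ERK is
    baseline + beta * (T - T_root).  Returns (records, expected ERK)."""
    rng = np.random.default_rng(seed)
    delta = config.beta * (temperature - config.root_temperature)
    freqs = tilt_frequencies(config.baseline_frequencies, delta)
    letters = np.array(list(AMINO_ACIDS))
    p = np.array([freqs[a] for a in AMINO_ACIDS])
    p = p / p.sum()
    lo, hi = config.length_range
    records = []
    for g in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=p))
        records.append(ProteinRecord(f"{species}_g{g}", seq))
    return records, expected_erk(freqs)


@dataclass
class Panel:
    """A full synthetic study panel with known truth."""

    tree: phylo.Phylogeny
    traits: pd.DataFrame  # species, temperature, group
    proteomes: dict[str, list[ProteinRecord]]
    expected_erk: dict[str, float]
    config: GeneratorConfig


def simulate_panel(config: GeneratorConfig | None = None) -> Panel:
    """Tree + BM temperatures + temperature-tilted proteomes."""
    cfg = config or GeneratorConfig()
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=cfg.seed)
    temps = simulate_bm_trait(
        tree, cfg.root_temperature, cfg.sigma2, seed=cfg.seed + 1, clamp=cfg.clamp
    )
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth: dict[str, float] = {}
    for i, sp in enumerate(sorted(temps)):
        proteomes[sp], truth[sp] = simulate_proteome(
            temps[sp], cfg, seed=cfg.seed + 1000 + i, species=sp
        )
    traits = pd.DataFrame(
        {
            "species": sorted(temps),
            "temperature": [temps[s] for s in sorted(temps)],
            "group": pd.NA,
        }
    )
    return Panel(tree, traits, proteomes, truth, cfg)


# -- coding sequences --------------------------------------------------------


def simulate_cds(
    proteome: Sequence[ProteinRecord], gc3: float = 0.5, seed: int = 0
) -> list[CdsRecord]:
    """Back-translate with third-position GC probability ``gc3``.

    For each residue, with probability gc3 a synonymous codon ending in G/C
    is chosen uniformly (falling back to A/T-ending codons when the amino
    acid has none), and conversely with probability 1-gc3.  Translation
    round-trips exactly.
    """
    if not 0 < gc3 < 1 and gc3 not in (0.0, 1.0):
        raise ValueError("gc3 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gc_end = {
        aa: [c for c in codons if c[2] in "GC"] for aa, codons in AA_TO_CODONS.items()
    }
    at_end = {
        aa: [c for c in codons if c[2] in "AT"] for aa, codons in AA_TO_CODONS.items()
    }
    out = []
    for rec in proteome:
        codons = []
        for aa in rec.sequence:
            want_gc = rng.random() < gc3
            pool = gc_end[aa] if want_gc else at_end[aa]
            if not pool:
                pool = at_end[aa] if want_gc else gc_end[aa]
            codons.append(pool[rng.integers(len(pool))])
        out.append(CdsRecord(rec.id, "".join(codons)))
    return out


# -- ortholog families and hit tables ---------------------------------------


@dataclass
class OrthologPanel:
    tree: phylo.Phylogeny
    traits: pd.DataFrame
    proteomes: dict[str, list[ProteinRecord]]
    #: family index -> {species: protein id}; the true orthology
    families: list[dict[str, str]]
    config: GeneratorConfig

    def hit_table(self, species_a: str, species_b: str) -> pd.DataFrame:
        return _hit_table(self.proteomes[species_a], self.proteomes[species_b])


def _encode(records: Sequence[ProteinRecord]) -> list[np.ndarray]:
    lut = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return [np.array([lut[c] for c in r.sequence], dtype=np.int8) for r in records]


def _hit_table(
    prots_a: Sequence[ProteinRecord],
    prots_b: Sequence[ProteinRecord],
    min_score: float = 30.0,
) -> pd.DataFrame:
    """All-against-all similarity in the reduced 6-column dialect.

    The score is 2 bits per identical position over the shorter sequence
    (ungapped — adequate for indel-free synthetic families); pairs below
    ``min_score`` bits are not reported, mimicking a search cutoff.
    """
    enc_a, enc_b = _encode(prots_a), _encode(prots_b)
    rows = []
    for i, ea in enumerate(enc_a):
        for j, eb in enumerate(enc_b):
            n = min(len(ea), len(eb))
            matches = int((ea[:n] == eb[:n]).sum())
            score = 2.0 * matches
            if score < min_score:
                continue
            evalue = float(n * 2.0 ** (-score))
            rows.append(
                (prots_a[i].id, prots_b[j].id, 100.0 * matches / n, n, evalue, score)
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def simulate_ortholog_panel(config: GeneratorConfig | None = None) -> OrthologPanel:
    """Gene families descending from single ancestors along the tree.

    Each family has one ancestral sequence drawn at the root composition;
    along every branch each site is replaced with probability
    1 - exp(-rate * length), the replacement drawn from the descendant
    species' temperature-tilted frequency vector (so proteome composition
    drifts with the trait).  True orthology is recorded per family.
    """
    cfg = config or GeneratorConfig()
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=cfg.seed)
    temps = simulate_bm_trait(
        tree, cfg.root_temperature, cfg.sigma2, seed=cfg.seed + 1, clamp=cfg.clamp
    )
    rng = np.random.default_rng(cfg.seed + 2)
    letters = np.array(list(AMINO_ACIDS))
    base_p = np.array([cfg.baseline_frequencies[a] for a in AMINO_ACIDS])
    base_p = base_p / base_p.sum()
    tilted: dict = {}
    for sp, T in temps.items():
        f = tilt_frequencies(cfg.baseline_frequencies, cfg.beta * (T - cfg.root_temperature))
        p = np.array([f[a] for a in AMINO_ACIDS])
        tilted[sp] = p / p.sum()
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in temps}
    families: list[dict[str, str]] = []
    for g in range(cfg.n_proteins):
        L = int(lengths[g])
        ancestor = rng.choice(len(letters), size=L, p=base_p)
        family: dict[str, str] = {}

        def descend(node, state):
            for child in node.child_nodes():
                p_sub = 1.0 - np.exp(-cfg.substitution_rate * child.edge.length)
                mask = rng.random(L) < p_sub
                new = state.copy()
                if child.is_leaf():
                    sp = child.taxon.label
                    new[mask] = rng.choice(len(letters), size=int(mask.sum()), p=tilted[sp])
                    pid = f"{sp}_f{g}"
                    proteomes[sp].append(
                        ProteinRecord(pid, "".join(letters[new]))
                    )
                    family[sp] = pid
                else:
                    new[mask] = rng.choice(len(letters), size=int(mask.sum()), p=base_p)
                    descend(child, new)

        descend(tree.tree.seed_node, ancestor)
        families.append(family)
    traits = pd.DataFrame(
        {
            "species": sorted(temps),
            "temperature": [temps[s] for s in sorted(temps)],
            "group": pd.NA,
        }
    )
    return OrthologPanel(tree, traits, proteomes, families, cfg)


# -- purpose-built scenario panels ------------------------------------------


def make_two_clade_tree(
    n_per_clade: int, stem_length: float = 200.0, inner_length: float = 1.0
) -> phylo.Phylogeny:
    """Two ladder-shaped clades of ``n_per_clade`` leaves joined by long stem
    branches; used for confounding scenarios where a clade-level shift must
    standardize into the contrast noise."""

    def ladder(labels: list[str]) -> str:
        # subtree without its own top branch length
        sub = f"{labels[0]}:{inner_length}"
        for lbl in labels[1:-1]:
            sub = f"({sub},{lbl}:{inner_length}):{inner_length}"
        return f"({sub},{labels[-1]}:{inner_length})"

    if n_per_clade < 2:
        raise ValueError("need at least 2 leaves per clade")
    a = ladder([f"a{i}" for i in range(1, n_per_clade + 1)])
    b = ladder([f"b{i}" for i in range(1, n_per_clade + 1)])
    return phylo.parse_newick(f"({a}:{stem_length},{b}:{stem_length});")


def simulate_confounded_panel(
    n_per_clade: int = 10,
    seed: int = 0,
    drifted_residue: str = "E",
    temp_offset: float = 20.0,
    freq_offset: float = 0.01,
    n_proteins: int = 30,
    protein_length: int = 200,
    within_sd: float = 2.0,
) -> Panel:
    """A panel where composition and temperature are linked only by descent.

    Clade "a" carries a temperature offset and an independent upward drift
    of one residue's frequency, both acquired on its long stem branch.
    A naive cross-species correlation sees two coincident clusters and calls
    the residue temperature-associated; independent contrasts divide the
    single informative difference by the long stem and find nothing.  There
    is no causal composition-temperature slope anywhere (beta = 0).
    """
    rng = np.random.default_rng(seed)
    tree = make_two_clade_tree(n_per_clade)
    base = default_frequencies()
    letters = np.array(list(AMINO_ACIDS))
    rows, proteomes, truth = [], {}, {}
    for sp in tree.leaf_labels:
        in_a = sp.startswith("a")
        temp = 30.0 + (temp_offset if in_a else 0.0) + rng.normal(0.0, within_sd)
        freqs = dict(base)
        if in_a:
            # move mass into the drifted residue, proportionally from the rest
            freqs[drifted_residue] += freq_offset
            for aa in AMINO_ACIDS:
                if aa != drifted_residue:
                    freqs[aa] -= freq_offset / 19.0
        p = np.array([freqs[a] for a in AMINO_ACIDS])
        p = p / p.sum()
        recs = [
            ProteinRecord(
                f"{sp}_g{g}", "".join(rng.choice(letters, size=protein_length, p=p))
            )
            for g in range(n_proteins)
        ]
        proteomes[sp] = recs
        truth[sp] = expected_erk(freqs)
        rows.append({"species": sp, "temperature": temp, "group": pd.NA})
    traits = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    return Panel(tree, traits, proteomes, truth, GeneratorConfig(seed=seed, beta=0.0))


def simulate_gc_confounded_orthologs(
    n_genes: int = 100,
    length: int = 120,
    n_swaps: int = 6,
    gc_changing: bool = True,
    gc3: float = 0.5,
    seed: int = 0,
) -> list[tuple[str, str, str, str, str]]:
    """Ortholog pairs whose ERK difference rides on E<->D substitutions.

    Side A keeps glutamate, side B has aspartate at ``n_swaps`` positions
    per gene; all other columns carry identical codons.  With
    ``gc_changing`` the E/D codons differ in G+C count (GAG vs GAT), so the
    GC-neutral filter removes every ERK-informative column and the matched
    ERK difference collapses to zero — the constructed null.  With
    ``gc_changing=False`` the codons are GC-matched (GAA vs GAT) and the
    ERK gap survives the filter.

    Returns (gene_id, aligned_a, aligned_b, cds_a, cds_b) tuples; the
    protein alignments are gap-free.
    """
    rng = np.random.default_rng(seed)
    base = default_frequencies()
    letters = np.array(list(AMINO_ACIDS))
    p = np.array([base[a] for a in AMINO_ACIDS])
    p = p / p.sum()
    codon_e = "GAG" if gc_changing else "GAA"  # GC 2 vs 1
    codon_d = "GAT"  # GC 1
    out = []
    for g in range(n_genes):
        prot = rng.choice(letters, size=length, p=p)
        (cds,) = simulate_cds(
            [ProteinRecord("x", "".join(prot))], gc3=gc3, seed=int(rng.integers(2**31))
        )
        codons = [cds.sequence[i : i + 3] for i in range(0, len(cds.sequence), 3)]
        codons_a, codons_b = list(codons), list(codons)
        prot_a, prot_b = list(prot), list(prot)
        positions = rng.choice(length, size=min(n_swaps, length), replace=False)
        for pos in positions:
            prot_a[pos], prot_b[pos] = "E", "D"
            codons_a[pos], codons_b[pos] = codon_e, codon_d
        out.append(
            (
                f"gene{g}",
                "".join(prot_a),
                "".join(prot_b),
                "".join(codons_a),
                "".join(codons_b),
            )
        )
    return out


def simulate_segment_pairs(
    n_segments: int = 500,
    shift_pp: float = 1.0,
    length: int = 150,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Aligned (gap-free) segment pairs where side A's composition is tilted
    ``shift_pp`` percentage points of ERK above side B; emulates the
    chicken-versus-reptile segment comparison at a chosen effect size."""
    rng = np.random.default_rng(seed)
    base = default_frequencies()
    fa = tilt_frequencies(base, shift_pp)
    letters = np.array(list(AMINO_ACIDS))
    pa = np.array([fa[a] for a in AMINO_ACIDS])
    pb = np.array([base[a] for a in AMINO_ACIDS])
    pa, pb = pa / pa.sum(), pb / pb.sum()
    return [
        (
            "".join(rng.choice(letters, size=length, p=pa)),
            "".join(rng.choice(letters, size=length, p=pb)),
        )
        for _ in range(n_segments)
    ]
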