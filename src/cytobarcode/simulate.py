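"""Synthetic data with the statistical structure the analyses assume.

Three generators cover the three data stages:

* ``simulate_genotypes`` draws per-larva inversion genotypes under exact
  Hardy-Weinberg proportions (binomial(2, q) per larva and inversion,
  independent across both), assigns sex by a fixed ratio, and sets
  nucleolar-organizer states to perfect Y-linkage unless an exception rate
  is configured;
* ``scramble_banding`` applies k uniformly random non-identity reversals to
  a banding sequence and returns the ground-truth scenario, giving
  instances with a known distance witness;
* ``simulate_k2p_alignment`` evolves sequences site-independently along a
  given tree under Kimura's two-parameter substitution model.

Defaults mirror the focal field sample: 19 larvae (9 females, 10 males),
the four observed autosomal inversion frequencies, a 7-reversal scramble of
an 18-fragment arm, and 658-bp alignments of 8 sequences.  A transition/
transversion ratio of 2 is used where the data give none, a conventional
value for insect mitochondrial COI.

Determinism: every generator derives its stream from (seed, component
index), so identical configs give byte-identical outputs and adding a call
to one generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .banding import BandingSequence, InversionStep, Scenario, apply_inversion
from .popgen import LarvaRecord

#: Component indices for per-generator random streams.
_STREAMS = {"genotypes": 0, "banding": 1, "alignment": 2}

#: Observed autosomal inversion frequencies in the focal sample.
DEFAULT_INVERSION_FREQS = {
    "IL us-1": 0.58,
    "IIL us-1": 0.10,
    "IIL us-2": 0.74,
    "IIIL ca, eu, em, Hi, us-1": 0.71,
}

#: Two four-leaf clusters, shallow within and deep between: the shape of a
#: barcode set containing a focal species plus near relatives.
DEFAULT_TREE = (
    "((t1:0.01,t2:0.01):0.06,(t3:0.01,t4:0.01):0.06,"
    "((t5:0.01,t6:0.01):0.06,(t7:0.01,t8:0.01):0.06):0.04);"
)


@dataclass
class SimConfig:
    """Parameters for all three generators; the seed is mandatory."""

    seed: int
    n_larvae: int = 19
    inversion_freqs: dict = field(default_factory=lambda: dict(DEFAULT_INVERSION_FREQS))
    sex_ratio: float = 9 / 19  # fraction female
    sex_exception_rate: float = 0.0
    scramble_k: int = 7
    tree: str = DEFAULT_TREE
    seq_length: int = 658
    ts_tv_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, q in self.inversion_freqs.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"frequency for {name} outside [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio outside [0, 1]")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.scramble_k < 0:
            raise ValueError("scramble_k must be >= 0")

    def rng(self, component: str) -> np.random.Generator:
        """Independent stream for one generator component."""
        return np.random.default_rng([int(self.seed), _STREAMS[component]])


def simulate_genotypes(cfg: SimConfig) -> list[LarvaRecord]:
    """Draw a larva table under exact HWE at the configured frequencies."""
    rng = cfg.rng("genotypes")
    n = cfg.n_larvae
    n_female = int(round(n * cfg.sex_ratio))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    names = sorted(cfg.inversion_freqs)
    # one draw matrix per inversion: number of inverted homologues in {0,1,2}
    draws = {name: rng.binomial(2, cfg.inversion_freqs[name], size=n) for name in names}
    genotype_code = {0: "ss", 1: "si", 2: "ii"}
    records = []
    for k in range(n):
        sex = sexes[k]
        state = "nucleolate_homozygous" if sex == "female" else "heterozygous"
        if cfg.sex_exception_rate > 0 and rng.random() < cfg.sex_exception_rate:
            state = "nucleolate_homozygous" if state == "heterozygous" else "heterozygous"
        records.append(
            LarvaRecord(
                larva_id=f"larva{k + 1:03d}",
                sex=sex,
                nucleolar_state=state,
                genotypes={name: genotype_code[int(draws[name][k])] for name in names},
            )
        )
    return records


def scramble_banding(
    ref: BandingSequence, k: int, seed: int
) -> tuple[BandingSequence, Scenario]:
    """Apply k uniformly random non-identity reversals; return result and true scenario."""
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng([int(seed), _STREAMS["banding"]])
    n = len(ref)
    state = ref
    steps: list[InversionStep] = []
    intermediates: list[BandingSequence] = []
    if n < 2 and k > 0:
        raise ValueError("cannot scramble a single-fragment sequence")
    for _ in range(k):
        # uniform over the n(n-1)/2 non-identity intervals
        i, j = (int(x) + 1 for x in np.sort(rng.choice(n, size=2, replace=False)))
        step = InversionStep(start=i, end=j)
        state = apply_inversion(state, step)
        steps.append(step)
        intermediates.append(state)
    return state, Scenario(steps=steps, start_seq=ref, intermediates=intermediates)


def _k80_probs(d: float, kappa: float) -> np.ndarray:
    """K80 site substitution matrix for a branch of length d (subs/site).

    Rows/cols in code order A, C, G, T; kappa is the transition/transversion
    *rate* ratio (kappa = 2 * ts_tv_ratio for equal-frequency K80).
    """
    # rates normalized so total substitution rate is 1 per unit branch length
    e1 = np.exp(-4.0 * d / (kappa + 2.0))
    e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
    P[0, 2] = P[2, 0] = p_ts  # A <-> G
    P[1, 3] = P[3, 1] = p_ts  # C <-> T
    return P


def simulate_k2p_alignment(cfg: SimConfig) -> list:
    """Evolve sequences along ``cfg.tree`` under the K2P model.

    Branch lengths are expected substitutions per site; the root sequence is
    uniform over A,C,G,T.  Returns a list of :class:`cytobarcode.phylo.AlignedSeq`
    in leaf-taxon order.
    """
    from .phylo import AlignedSeq

    rng = cfg.rng("alignment")
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    kappa = 2.0 * cfg.ts_tv_ratio
    L = cfg.seq_length
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out = []
    alphabet = np.array(list("ACGT"))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_seq = seqs[id(node.parent_node)]
            d = node.edge.length or 0.0
            if d <= 0:
                child_seq = parent_seq.copy()
            else:
                P = _k80_probs(d, kappa)
                cum = P.cumsum(axis=1)
                u = rng.random(L)
                child_seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
            seqs[id(node)] = child_seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(out) + 1}"
            out.append(AlignedSeq(id=label.replace(" ", "_"),
                                  residues="".join(alphabet[seqs[id(node)]])))
    return out
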