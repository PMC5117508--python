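"""Synthetic benchmark data with known ground truth.

Emulates the study design the pipeline targets: a protein-association
network with dense functional modules (planted-partition graph with
STRING-style confidence scores), pathway annotations covering the modules,
replicate log2 expression per sample class with class-specific shifts
concentrated in chosen modules, and raw probe tables for the preprocessing
chain.  Every artifact is fully determined by (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_annotations",
    "generate_expression",
    "generate_raw_probes",
]


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for one synthetic dataset."""

    module_of: dict[str, int]  # gene -> module id
    n_modules: int
    edge_confidences: dict[str, float] = field(default_factory=dict)  # "a|b" -> confidence
    perturbations: dict[str, dict[int, float]] = field(default_factory=dict)  # class -> {module: fold}
    noise_sd: float = 0.0
    seeds: dict[str, int] = field(default_factory=dict)
    below_lod_probes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.module_of)

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m == module)

    def n_edges_above(self, threshold: float) -> int:
        """Edges strictly above a confidence threshold (loader semantics)."""
        return sum(1 for c in self.edge_confidences.values() if c > threshold)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["perturbations"] = {
            cls: {str(m): f for m, f in eff.items()} for cls, eff in self.perturbations.items()
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, "rt") as fh:
            payload = json.load(fh)
        payload["module_of"] = {g: int(m) for g, m in payload["module_of"].items()}
        payload["perturbations"] = {
            c: {int(m): float(f) for m, f in eff.items()}
            for c, eff in payload["perturbations"].items()
        }
        return cls(**payload)


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}" if a < b else f"{b}|{a}"


def generate_network(
    n_modules: int = 4,
    module_size: int = 15,
    p_in: float = 0.9,
    p_out: float = 0.02,
    conf_in: tuple[float, float] = (0.85, 0.999),
    conf_out: tuple[float, float] = (0.4, 0.95),
    threshold: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Planted-partition association network with confidence scores.

    Within-module pairs get an edge with probability ``p_in`` and a
    confidence drawn from ``Uniform(*conf_in)``; between-module pairs use
    ``p_out`` and ``Uniform(*conf_out)``, so thresholding at 0.8 keeps most
    within-module and few between-module edges.  Genes left isolated above
    ``threshold`` are re-wired to a random same-module partner with a
    high-confidence edge, guaranteeing degree >= 1 after loading.  Gene
    names are zero-padded, so the lexicographic gene order equals the
    planted module blocks.

    Returns the edge table (``gene_a, gene_b, confidence``) and the truth
    record.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_modules < 1 or module_size < 2:
        raise ValueError("need n_modules >= 1 and module_size >= 2")
    rng = np.random.default_rng(seed)
    n = n_modules * module_size
    width = max(4, len(str(n - 1)))
    genes = [f"g{i:0{width}d}" for i in range(n)]
    module = np.arange(n) // module_size
    confs: dict[str, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            same = module[i] == module[j]
            if rng.random() < (p_in if same else p_out):
                lo, hi = conf_in if same else conf_out
                confs[_pair_key(genes[i], genes[j])] = float(rng.uniform(lo, hi))
    # guarantee every gene keeps at least one association after thresholding
    degree_above = {g: 0 for g in genes}
    for key, c in confs.items():
        if c > threshold:
            a, b = key.split("|")
            degree_above[a] += 1
            degree_above[b] += 1
    for i, g in enumerate(genes):
        if degree_above[g] == 0:
            mates = [genes[j] for j in range(n) if j != i and module[j] == module[i]]
            mate = mates[int(rng.integers(len(mates)))]
            confs[_pair_key(g, mate)] = float(rng.uniform(*conf_in))
            degree_above[g] += 1
            degree_above[mate] += 1
    rows = sorted((k.split("|")[0], k.split("|")[1], c) for k, c in confs.items())
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    truth = SyntheticTruth(
        module_of={g: int(m) for g, m in zip(genes, module)},
        n_modules=n_modules,
        edge_confidences=confs,
        seeds={"network": seed},
    )
    return edges, truth


def generate_annotations(
    truth: SyntheticTruth, include_super_terms: bool = False
) -> dict[str, list[str]]:
    """Gene sets mirroring the planted modules (GMT-ready).

    One set per module; with ``include_super_terms`` additional sets span
    consecutive module pairs, mimicking broad ontology terms that overlap
    several functional modules.
    """
    sets = {
        f"module_{m:02d}": truth.module_genes(m) for m in range(truth.n_modules)
    }
    if include_super_terms:
        for m in range(truth.n_modules - 1):
            sets[f"super_{m:02d}_{m + 1:02d}"] = truth.module_genes(m) + truth.module_genes(m + 1)
    return sets


def generate_expression(
    truth: SyntheticTruth,
    classes: Sequence[str] = ("R", "P"),
    n_replicates: int = 3,
    baseline: float = 8.0,
    effects: Optional[Mapping[str, Mapping[int, float]]] = None,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate log2 expression with class-specific module shifts.

    Values are ``baseline + log2(fold) + N(0, noise_sd)`` where ``fold`` is
    the multiplicative effect configured for the sample's class and the
    gene's module (default: none).  ``effects`` maps class -> {module id ->
    fold}; e.g. ``{"P": {2: 1.5}}`` plants a 1.5x up-shift of module 2 in
    class P.  Returns (genes x samples matrix, sample -> class labels).
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2 for within-class variance")
    effects = {c: dict(e) for c, e in (effects or {}).items()}
    rng = np.random.default_rng(seed)
    genes = truth.genes
    module = np.array([truth.module_of[g] for g in genes])
    columns, labels = [], {}
    data = {}
    for cls in classes:
        shift = np.zeros(len(genes))
        for m, fold in effects.get(cls, {}).items():
            if fold <= 0:
                raise ValueError("multiplicative effects must be positive")
            shift[module == m] = np.log2(fold)
        for k in range(n_replicates):
            name = f"{cls}_{k + 1}"
            data[name] = baseline + shift + rng.normal(0.0, noise_sd, size=len(genes))
            labels[name] = cls
            columns.append(name)
    expr = pd.DataFrame(data, index=genes)[columns]
    truth.perturbations = {c: {int(m): float(f) for m, f in e.items()} for c, e in effects.items()}
    truth.noise_sd = float(noise_sd)
    truth.seeds["expression"] = seed
    lab = pd.Series(labels, name="class")
    lab.index.name = "sample"
    return expr, lab


def generate_raw_probes(
    expression: pd.DataFrame,
    probes_per_gene: int = 3,
    n_negative_controls: int = 50,
    below_lod_fraction: float = 0.0,
    probe_jitter_sd: float = 0.1,
    background_log2: float = 4.0,
    control_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Expand a gene-level log2 matrix into a raw probe intensity table.

    Each gene gets ``probes_per_gene`` probes whose linear intensities are
    ``2**(value + jitter)``.  Negative-control probes sit at the background
    level; a fraction of gene probes is planted far below the implied limit
    of detection so the detection filter has known targets.  Returns the raw
    table (columns ``probe, is_negative_control, gene, <samples>``) and the
    list of planted below-LoD probe ids.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if not 0.0 <= below_lod_fraction < 1.0:
        raise ValueError("below_lod_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = list(expression.columns)
    records = []
    probe_ids = []
    for g in expression.index:
        for k in range(probes_per_gene):
            probe_ids.append(f"{g}_p{k}")
    n_probes = len(probe_ids)
    n_low = int(round(below_lod_fraction * n_probes))
    low_idx = set(rng.choice(n_probes, size=n_low, replace=False).tolist()) if n_low else set()
    below_lod: list[str] = []
    i = 0
    for g in expression.index:
        base = expression.loc[g].to_numpy(dtype=np.float64)
        for k in range(probes_per_gene):
            pid = probe_ids[i]
            if i in low_idx:
                log2_vals = rng.normal(background_log2 - 2.0, 0.1, size=len(samples))
                below_lod.append(pid)
            else:
                log2_vals = base + rng.normal(0.0, probe_jitter_sd, size=len(samples))
            records.append([pid, False, g] + list(2.0 ** log2_vals))
            i += 1
    for k in range(n_negative_controls):
        log2_vals = rng.normal(background_log2, control_sd, size=len(samples))
        records.append([f"neg_ctrl_{k:03d}", True, ""] + list(2.0 ** log2_vals))
    table = pd.DataFrame(records, columns=["probe", "is_negative_control", "gene"] + samples)
    return table, below_lod
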