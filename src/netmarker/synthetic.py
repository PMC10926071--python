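"""Synthetic expression data with planted modules, hubs and stage effects.

A latent-factor generator: each planted module m has one factor per
sample, f_{m,s} = shift(group(s), m) + N(0,1), and a gene g of the
module reads lambda_g * f_{m,s} + noise_sd * eps with the hub carrying a
higher loading than ordinary members. Noise genes are pure low-variance
Gaussians. Group shifts follow fixed orthogonal sign patterns (Hadamard
rows) scaled by ``group_effect``, so disease stages separate along every
module factor. The closed-form within-module correlation
lambda_a*lambda_b / sqrt((lambda_a^2+s^2)(lambda_b^2+s^2)) makes the
generator testable against theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from netmarker.expression_io import GROUPS, ExpressionMatrix, SampleAnnotation

#: the three non-constant Hadamard contrasts over the four stage groups
#: (rows ordered as GROUPS); they span the zero-sum "group contrast" space
_CONTRASTS = np.array(
    [
        [1, 1, 1],
        [-1, 1, -1],
        [1, -1, -1],
        [-1, -1, 1],
    ],
    dtype=float,
)

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
#: icosahedral axis directions in the 3-d contrast space: any two distinct
#: axes have |cos| = 1/sqrt(5), the best-spread packing of 6 lines in 3-d
_ICOSAHEDRAL = np.array(
    [
        [0, 1, -_PHI],
        [1, _PHI, 0],
        [1, -_PHI, 0],
        [_PHI, 0, 1],
        [-_PHI, 0, 1],
        [0, 1, _PHI],
    ],
    dtype=float,
)
_ICOSAHEDRAL /= np.linalg.norm(_ICOSAHEDRAL, axis=1, keepdims=True)


def group_shift_pattern(module: int) -> np.ndarray:
    """Per-group factor shift (unit scale) for one module.

    Each module's stage effect points along its own direction of the
    group-contrast space; directions are icosahedral so any two modules
    share at most |cos| = 1/sqrt(5) of their stage signal (cycled beyond
    six modules). Multiply by ``group_effect`` for the actual shift.
    """
    direction = _ICOSAHEDRAL[(module - 1) % len(_ICOSAHEDRAL)]
    return _CONTRASTS @ direction


@dataclass
class SimulationConfig:
    """Generator settings; the defaults emulate a small microarray cohort
    (31 samples in 4 stage groups, ~10^3 genes of which a minority are
    disease-sensitive and organized into 5 hub-anchored modules)."""

    n_modules: int = 5
    genes_per_module: int = 30
    n_noise_genes: int = 850
    hub_loading: float = 0.95
    member_loading: float = 0.6
    noise_sd: float = 0.5
    noise_gene_sd: float = 0.5
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 9, "incipient": 7, "moderate": 8, "severe": 7}
    )
    group_effect: float = 1.5
    exponentiate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.member_loading <= self.hub_loading <= 1):
            raise ValueError("need 0 < member_loading <= hub_loading <= 1")
        if self.n_modules < 1 or self.genes_per_module < 2:
            raise ValueError("need at least 1 module with 2 genes")
        bad = set(self.group_sizes) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")

    @property
    def n_sensitive(self) -> int:
        return self.n_modules * self.genes_per_module

    @property
    def n_genes(self) -> int:
        return self.n_sensitive + self.n_noise_genes

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class GroundTruth:
    sensitive_genes: list[str]
    modules: pd.Series  # gene -> planted module id (sensitive genes only)
    hubs: dict[int, str]  # module id -> hub gene
    groups: pd.Series  # sample -> group

    def __post_init__(self) -> None:
        for m, hub in self.hubs.items():
            if self.modules.get(hub) != m:
                raise ValueError(f"hub {hub} not a member of module {m}")


def hub_gene_name(module: int) -> str:
    return f"M{module:02d}_HUB"


def member_gene_name(module: int, j: int) -> str:
    return f"M{module:02d}_G{j:02d}"


def simulate(config: SimulationConfig, seed: int | None = None) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression matrix plus its ground truth. Deterministic per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups_order = [g for g in GROUPS if g in config.group_sizes]
    sample_groups: list[str] = []
    for g in groups_order:
        sample_groups.extend([g] * config.group_sizes[g])
    n_samples = len(sample_groups)
    sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    groups = pd.Series(sample_groups, index=sample_ids, name="group")
    group_index = {g: i for i, g in enumerate(GROUPS)}

    gene_ids: list[str] = []
    values = np.empty((config.n_genes, n_samples))
    modules: dict[str, int] = {}
    hubs: dict[int, str] = {}
    row = 0
    for m in range(1, config.n_modules + 1):
        pattern = group_shift_pattern(m)
        shifts = np.array(
            [config.group_effect * pattern[group_index[g]] for g in sample_groups]
        )
        factor = shifts + rng.standard_normal(n_samples)
        hub = hub_gene_name(m)
        hubs[m] = hub
        loadings = [config.hub_loading] + [config.member_loading] * (
            config.genes_per_module - 1
        )
        names = [hub] + [
            member_gene_name(m, j) for j in range(1, config.genes_per_module)
        ]
        for name, lam in zip(names, loadings):
            values[row] = lam * factor + config.noise_sd * rng.standard_normal(n_samples)
            gene_ids.append(name)
            modules[name] = m
            row += 1
    for j in range(config.n_noise_genes):
        values[row] = config.noise_gene_sd * rng.standard_normal(n_samples)
        gene_ids.append(f"N{j:04d}")
        row += 1
    if config.exponentiate:
        # mimic raw microarray intensities; log2(x+1) roughly inverts this
        values = np.exp2(values + 8.0)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        annotation=SampleAnnotation(groups=groups),
    )
    truth = GroundTruth(
        sensitive_genes=[g for g in gene_ids if g in modules],
        modules=pd.Series(modules, name="module"),
        hubs=hubs,
        groups=groups,
    )
    return expr, truth


def score_recovery(
    truth: GroundTruth,
    selected_genes: list[str] | None = None,
    partition: pd.Series | None = None,
    representatives: list[str] | None = None,
    predictions: pd.Series | None = None,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Reports sensitive-gene recall/precision, adjusted Rand agreement
    between planted and inferred modules (on the genes present in both),
    the fraction of planted hubs appearing among the representatives, and
    subtype accuracy against the planted groups. Only the sections whose
    inputs are supplied are filled.
    """
    out: dict[str, float] = {}
    if selected_genes is not None:
        sel = set(selected_genes)
        planted = set(truth.sensitive_genes)
        out["sensitive_recall"] = len(sel & planted) / len(planted)
        out["sensitive_precision"] = len(sel & planted) / len(sel) if sel else 0.0
    if partition is not None:
        shared = [g for g in partition.index if g in truth.modules.index]
        if shared:
            out["module_ari"] = float(
                adjusted_rand_score(
                    truth.modules.reindex(shared), partition.reindex(shared)
                )
            )
        else:
            out["module_ari"] = 0.0
    if representatives is not None:
        hubs = set(truth.hubs.values())
        out["hub_recovery"] = len(set(representatives) & hubs) / len(hubs)
    if predictions is not None:
        ref = truth.groups.reindex(predictions.index)
        out["subtype_accuracy"] = float((predictions == ref).mean())
    return out


def write_truth(truth: GroundTruth, directory: str) -> None:
    """Write ground-truth TSVs (modules, hubs, groups) into a directory."""
    import os

    truth.modules.rename_axis("gene").reset_index().to_csv(
        os.path.join(directory, "truth_modules.tsv"), sep="\t", index=False
    )
    pd.Series(truth.hubs, name="hub").rename_axis("module").reset_index().to_csv(
        os.path.join(directory, "truth_hubs.tsv"), sep="\t", index=False
    )
    truth.groups.rename_axis("sample_id").reset_index().to_csv(
        os.path.join(directory, "truth_groups.tsv"), sep="\t", index=False
    )
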