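"""Synthetic OTU-table generator with known ground truth.

Emulates an 18-sample 16S survey of three habitats (water, sediment,
crayfish intestine) under two breeding modes (MC monoculture ponds, RC
rice co-culture fields), three replicates each, with per-sample depths in
the ~33,000-45,000 read range.

The community model is a log-normal copula: per sample a latent Gaussian
vector is drawn with block (equicorrelated) correlation inside each planted
module, exponentiated with habitat/mode log-mean offsets to give log-normal
relative abundances, closed to proportions, and realised as a multinomial
draw at the sample's depth.  Because exp() is monotone, the latent rank
correlation survives the transform, so Spearman-based network recovery on
the output is well-posed.  The ground truth (module membership, latent
correlation matrix, signature habitats) is retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import HABITATS, MODES

__all__ = ["SynthConfig", "GroundTruth", "generate_community", "planted_edge_set", "write_simulation"]

#: one-letter habitat codes used in sample ids (MCw1, RCs2, MCc3, ...)
_HABITAT_CODE = {"water": "w", "sediment": "s", "intestine": "c"}

#: phyla cycled through when inventing taxonomy strings
_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Tenericutes", "Firmicutes",
    "Cyanobacteria", "Chloroflexi", "Bacteroidetes", "Acidobacteria",
    "RsaHF231", "Nitrospirae",
)


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of the generator.

    ``n_taxa_per_habitat_signature`` may be a single count or a mapping
    habitat -> count (the mapping form expresses richness gradients such as
    sediment > water > intestine).  ``habitat_effect_logfold`` is the
    natural-log separation of a signature taxon's mean between its home
    habitat and the others; ``mode_effect_logfold`` (default 0: the null)
    shifts the first half of the shared taxa in the second mode's samples.
    """

    n_replicates_per_group: int = 3
    habitats: tuple[str, ...] = HABITATS
    modes: tuple[str, ...] = MODES
    depth_range: tuple[int, int] = (33_000, 45_000)
    n_taxa_per_habitat_signature: int | Mapping[str, int] = 40
    n_shared_taxa: int = 120
    n_modules: int = 3
    within_module_latent_correlation: float = 0.9
    habitat_effect_logfold: float = 3.0
    mode_effect_logfold: float = 0.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def signature_sizes(self) -> dict[str, int]:
        if isinstance(self.n_taxa_per_habitat_signature, Mapping):
            return {h: int(self.n_taxa_per_habitat_signature[h]) for h in self.habitats}
        return {h: int(self.n_taxa_per_habitat_signature) for h in self.habitats}

    @property
    def n_taxa(self) -> int:
        return sum(self.signature_sizes().values()) + self.n_shared_taxa

    def validate(self) -> None:
        lo, hi = self.depth_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid depth_range {self.depth_range}")
        if self.n_replicates_per_group < 1:
            raise ValueError("n_replicates_per_group must be >= 1")
        sizes = self.signature_sizes()
        if any(s < 1 for s in sizes.values()) or self.n_shared_taxa < 0:
            raise ValueError("taxon counts must be positive")
        if self.n_taxa < self.n_modules:
            raise ValueError(
                f"{self.n_taxa} taxa cannot host {self.n_modules} modules"
            )
        if self.n_modules > len(self.habitats):
            raise ValueError(
                f"n_modules={self.n_modules} exceeds the {len(self.habitats)} "
                "habitats (modules are planted on habitat signature sets)"
            )
        rho = self.within_module_latent_correlation
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"within_module_latent_correlation must be in [0,1), got {rho}")
        for m in range(self.n_modules):
            k = sizes[self.habitats[m]]
            if k > 1 and rho <= -1.0 / (k - 1):
                raise ValueError(
                    f"correlation block for module {m} (size {k}) is not positive semi-definite"
                )
        if self.habitat_effect_logfold < 0 or self.mode_effect_logfold < 0:
            raise ValueError("effect log-folds must be non-negative")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: used as the oracle in recovery tests.

    ``module_membership`` maps each taxon to its planted module id, with -1
    for taxa outside every module.  ``signature_habitat`` maps each taxon to
    its home habitat or ``"shared"``.
    """

    module_membership: dict[str, int]
    latent_correlation_matrix: pd.DataFrame
    signature_habitat: dict[str, str]

    def validate(self) -> None:
        m = self.latent_correlation_matrix.to_numpy()
        if not np.allclose(m, m.T):
            raise ValueError("latent correlation matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("latent correlation matrix diagonal != 1")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("latent correlation matrix not positive semi-definite")


def _taxon_name(habitat: str, i: int) -> str:
    stem = f"{habitat.capitalize()}ibacter_{i:03d}" if habitat != "shared" else f"Communis_{i:03d}"
    if i % 7 == 3:
        return f"unclassified_f__{stem}"
    if i % 3 == 0:
        return f"norank_f__{stem}"
    return stem


def _layout(config: SynthConfig):
    """Taxon ids, names, signature habitats and module membership."""
    sizes = config.signature_sizes()
    taxon_ids, genera, signature, modules = [], [], {}, {}
    idx = 0
    for m, hab in enumerate(config.habitats):
        for i in range(sizes[hab]):
            tid = f"t{idx:04d}"
            taxon_ids.append(tid)
            genera.append(_taxon_name(hab, i))
            signature[tid] = hab
            modules[tid] = m if m < config.n_modules else -1
            idx += 1
    for i in range(config.n_shared_taxa):
        tid = f"t{idx:04d}"
        taxon_ids.append(tid)
        genera.append(_taxon_name("shared", i))
        signature[tid] = "shared"
        modules[tid] = -1
        idx += 1
    return taxon_ids, genera, signature, modules


def generate_community(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic data set: (count table, taxonomy, metadata, truth).

    One sample per (mode, habitat, replicate) triple; per-sample totals are
    uniform on ``depth_range``.  Bit-identical output under the same config
    (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxon_ids, genera, signature, modules = _layout(config)
    t = len(taxon_ids)
    rho = config.within_module_latent_correlation

    # latent correlation matrix: equicorrelated blocks on the diagonal
    corr = np.eye(t)
    for m in range(config.n_modules):
        idx = [i for i, tid in enumerate(taxon_ids) if modules[tid] == m]
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = rho
    corr_df = pd.DataFrame(corr, index=taxon_ids, columns=taxon_ids)

    # sample design, paper-style ids: MCw1 ... RCc3
    samples = []
    for mode in config.modes:
        for hab in config.habitats:
            for rep in range(1, config.n_replicates_per_group + 1):
                samples.append((f"{mode}{_HABITAT_CODE.get(hab, hab[0])}{rep}", hab, mode, rep))
    sample_ids = [s[0] for s in samples]

    # log-mean offsets
    mu = np.zeros((t, len(samples)))
    sig_rows = {hab: [i for i, tid in enumerate(taxon_ids) if signature[tid] == hab]
                for hab in config.habitats}
    shared_rows = [i for i, tid in enumerate(taxon_ids) if signature[tid] == "shared"]
    mode_rows = shared_rows[: len(shared_rows) // 2]
    for j, (_, hab, mode, _) in enumerate(samples):
        mu[sig_rows[hab], j] += config.habitat_effect_logfold
        if mode == config.modes[-1] and config.mode_effect_logfold:
            mu[mode_rows, j] += config.mode_effect_logfold

    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=len(samples))
    module_rows = [
        [i for i, tid in enumerate(taxon_ids) if modules[tid] == m]
        for m in range(config.n_modules)
    ]
    counts = np.zeros((t, len(samples)), dtype=np.int64)
    sqrho, sqres = np.sqrt(rho), np.sqrt(1.0 - rho)
    for j in range(len(samples)):
        z = rng.standard_normal(t)
        commons = rng.standard_normal(config.n_modules)
        for m, rows in enumerate(module_rows):
            z[rows] = sqrho * commons[m] + sqres * z[rows]
        w = np.exp(mu[:, j] + config.lognormal_sigma * z)
        p = w / w.sum()  # compositional closure before sampling
        counts[:, j] = rng.multinomial(depths[j], p)

    table = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    table.index.name = "taxon_id"
    phyla = [_PHYLA[i % len(_PHYLA)] for i in range(t)]
    taxonomy = pd.DataFrame({"phylum": phyla, "genus": genera}, index=taxon_ids)
    taxonomy.index.name = "taxon_id"
    info = pd.DataFrame(
        {
            "habitat": [s[1] for s in samples],
            "mode": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(dict(modules), corr_df, dict(signature))
    return table, taxonomy, info, truth


def planted_edge_set(truth: GroundTruth, min_latent_rho: float) -> list[tuple[str, str]]:
    """Unordered taxon pairs whose planted latent correlation is >= threshold.

    This is the ground-truth edge list that network recovery is scored
    against (sensitivity/precision of the thresholded Spearman network).
    """
    if not (0.0 < min_latent_rho < 1.0):
        raise ValueError(f"min_latent_rho must be in (0,1), got {min_latent_rho}")
    m = truth.latent_correlation_matrix
    taxa = list(m.index)
    vals = m.to_numpy()
    edges = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if vals[i, j] >= min_latent_rho:
                edges.append(tuple(sorted((taxa[i], taxa[j]))))
    return sorted(edges)


def write_simulation(
    outdir,
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    info: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write the four TSVs plus ground-truth files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "otu_table.tsv", sep="\t")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    info.to_csv(outdir / "metadata.tsv", sep="\t")
    membership = pd.DataFrame(
        {
            "module": pd.Series(truth.module_membership),
            "signature_habitat": pd.Series(truth.signature_habitat),
        }
    )
    membership.index.name = "taxon_id"
    membership.to_csv(outdir / "truth_modules.tsv", sep="\t")
    truth.latent_correlation_matrix.to_csv(outdir / "truth_correlation.tsv", sep="\t")
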