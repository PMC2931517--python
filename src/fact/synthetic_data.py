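"""Seeded generator of feature catalogs and proteomes with planted families.

The generator emulates the structure of a pre-annotated proteome used
for functional-equivalence benchmarking: a feature catalog with Pfam-like
domains (a configurable fraction clan-assigned), SMART-like domains and
a fixed repertoire of structural/compositional annotations; and
*planted families* — groups of proteins sharing a core architecture,
standing in for same-function proteins, scattered among unrelated
decoys.  Family members receive a shared four-field dotted label (the
shape of an EC number) so the evaluation module runs unchanged on
synthetic data.

Two distributional choices mirror real proteomes.  Background (decoy)
feature usage is skewed: structural/compositional annotations are the
most frequent feature classes (transmembrane segments, helices and
low-complexity regions occur in a large share of proteins) and domain
frequencies fall off as a power law, so a few promiscuous domains
dominate the background.  Family cores, in contrast, are *specific*
domain combinations sampled uniformly from the domain catalog —
a family is defined by which domains it combines, not by how common
those domains are — optionally extended by one ubiquitous structural
feature.

Within a family the protein length is constant and, at zero noise,
members are identical, so every pairwise similarity component is exactly
1.  Noise drops instances, adds spurious ones and jitters instance
centers (lengths preserved, clipped to protein bounds).  Each family
core is anchored on at least one clan-assigned Pfam domain whenever the
catalog contains any, so identical members also reach clan similarity 1.

Sequences are not simulated; the generator covers architecture-level
behaviour only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .architecture_model import (
    FeatureArchitecture,
    FeatureCatalog,
    FeatureInstance,
)
from .annotation_io import Proteome, write_architecture_tables

__all__ = ["GeneratorConfig", "generate_catalog", "generate_proteome",
           "write_synthetic_dataset"]

#: Canonical ids of structural/compositional annotation classes.
STRUCTURAL_FEATURES = (
    "tmhmm:TM",
    "signalp:SP",
    "coils:CC",
    "phd:H",
    "phd:E",
    "seg:LC",
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic proteome.

    Defaults describe the study conditions used throughout the test
    suite: 500 proteins, 50 planted families of 3, moderately noisy
    family copies (10% instance drop, 5% spurious addition, positional
    jitter 5% of protein length), and a power-law feature frequency
    with exponent 1.5.
    """

    n_proteins: int = 500
    n_pfam: int = 80
    n_smart: int = 30
    include_structural: bool = True
    n_clans: int = 10
    clan_prob: float = 0.6
    freq_skew: float = 1.5
    mean_instances: float = 4.0
    length_min: int = 100
    length_max: int = 1000
    n_families: int = 50
    family_size: int = 3
    core_features_min: int = 3
    core_features_max: int = 6
    structural_in_core: float = 0.5
    dup_prob: float = 0.15
    drop_prob: float = 0.1
    add_prob: float = 0.05
    jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("clan_prob", "structural_in_core", "dup_prob",
                     "drop_prob", "add_prob", "jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_proteins, self.n_pfam, self.n_families,
               self.family_size, self.length_min) <= 0:
            raise ValueError("sizes must be positive")
        if self.n_families * self.family_size > self.n_proteins:
            raise ValueError(
                "planted families do not fit: "
                f"{self.n_families} × {self.family_size} > {self.n_proteins}"
            )
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")


def _feature_universe(cfg: GeneratorConfig) -> List[str]:
    """Feature types in background-frequency rank order.

    Structural/compositional classes come first so the power-law
    background makes them the most frequent annotations, as in real
    proteomes; domains follow, so a handful of leading Pfam/SMART
    families act as the promiscuous domains of the background.
    """
    pfam = [f"pfam:PF{i + 1:05d}" for i in range(cfg.n_pfam)]
    smart = [f"smart:SM{i + 1:05d}" for i in range(cfg.n_smart)]
    structural = list(STRUCTURAL_FEATURES) if cfg.include_structural else []
    return structural + pfam + smart


def generate_catalog(cfg: GeneratorConfig) -> FeatureCatalog:
    """Clan-assign a fraction of the Pfam features, deterministically."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    clan_of: Dict[str, str] = {}
    clans = [f"CL{i + 1:04d}" for i in range(cfg.n_clans)]
    for i in range(cfg.n_pfam):
        if cfg.n_clans > 0 and rng.random() < cfg.clan_prob:
            clan_of[f"pfam:PF{i + 1:05d}"] = clans[int(rng.integers(cfg.n_clans))]
    return FeatureCatalog(clan_of, pfam_namespaces={"pfam"})


def _frequency_weights(cfg: GeneratorConfig, n: int) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** -cfg.freq_skew if cfg.freq_skew > 0 else np.ones(n)
    return w / w.sum()


@dataclass
class _CoreInstance:
    feature_id: str
    rel_center: float
    rel_span: float


def _instantiate(
    core: List[_CoreInstance], length: int, jitter_sd: float, rng
) -> List[FeatureInstance]:
    out: List[FeatureInstance] = []
    for ci in core:
        center = ci.rel_center
        if jitter_sd > 0:
            center += rng.normal(0.0, jitter_sd)
        span = max(1, round(ci.rel_span * length))
        start = round(center * length - span / 2)
        start = min(max(start, 1), length - span + 1)
        out.append(FeatureInstance(ci.feature_id, start, start + span - 1))
    return out


def _random_instance(length: int, feature_id: str, rng) -> FeatureInstance:
    span = max(1, round(float(rng.uniform(0.03, 0.3)) * length))
    start = int(rng.integers(1, length - span + 2))
    return FeatureInstance(feature_id, start, start + span - 1)


def _family_code(k: int) -> str:
    return f"{k % 6 + 1}.{k // 6 + 1}.{k + 1}.1"


def _decoy_code(i: int) -> str:
    return f"9.{i + 1}.{i + 1}.1"


def generate_proteome(
    cfg: GeneratorConfig, catalog: Optional[FeatureCatalog] = None
) -> Tuple[Proteome, Dict[str, Optional[int]], Dict[str, str]]:
    """Generate the proteome, family membership and family-style labels.

    Returns ``(proteome, family_of, labels)``: ``family_of`` maps each
    protein id to its planted family index (``None`` for decoys);
    ``labels`` maps each protein id to a four-field dotted code shared
    within a family and unique per decoy.
    """
    cfg.validate()
    if catalog is None:
        catalog = generate_catalog(cfg)
    rng = np.random.default_rng((cfg.seed, 1))
    universe = _feature_universe(cfg)
    weights = _frequency_weights(cfg, len(universe))
    domain_pool = [
        f for f in universe if f.partition(":")[0] in ("pfam", "smart")
    ]
    structural_pool = [f for f in universe if f not in domain_pool]
    clan_anchored = [f for f in domain_pool if catalog.clan(f) is not None]

    archs: List[FeatureArchitecture] = []
    family_of: Dict[str, Optional[int]] = {}
    labels: Dict[str, str] = {}

    for fam in range(cfg.n_families):
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        k = int(rng.integers(cfg.core_features_min, cfg.core_features_max + 1))
        k = min(k, len(domain_pool))
        # a family is a specific domain combination: uniform over the
        # domain catalog, anchored on one clan-assigned Pfam domain
        chosen = [str(f) for f in rng.choice(domain_pool, size=k, replace=False)]
        if clan_anchored and not set(chosen) & set(clan_anchored):
            chosen[0] = str(rng.choice(clan_anchored))
        if structural_pool and rng.random() < cfg.structural_in_core:
            chosen.append(str(rng.choice(structural_pool)))
        core: List[_CoreInstance] = []
        for feature_id in sorted(set(chosen)):
            copies = 2 if rng.random() < cfg.dup_prob else 1
            for _ in range(copies):
                core.append(
                    _CoreInstance(
                        feature_id=feature_id,
                        rel_center=float(rng.uniform(0.05, 0.95)),
                        rel_span=float(rng.uniform(0.03, 0.25)),
                    )
                )
        for m in range(cfg.family_size):
            pid = f"F{fam:03d}_{m}"
            kept = [
                ci for ci in core if cfg.drop_prob == 0 or rng.random() >= cfg.drop_prob
            ]
            if not kept:  # never emit a featureless family member
                kept = [core[int(rng.integers(len(core)))]]
            insts = _instantiate(kept, length, cfg.jitter, rng)
            if cfg.add_prob > 0 and rng.random() < cfg.add_prob:
                extra = universe[int(rng.choice(len(universe), p=weights))]
                insts.append(_random_instance(length, extra, rng))
            archs.append(FeatureArchitecture(pid, length, insts))
            family_of[pid] = fam
            labels[pid] = _family_code(fam)

    n_decoys = cfg.n_proteins - cfg.n_families * cfg.family_size
    for i in range(n_decoys):
        pid = f"D{i:04d}"
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        n_inst = int(rng.poisson(cfg.mean_instances))
        insts = [
            _random_instance(
                length, universe[int(rng.choice(len(universe), p=weights))], rng
            )
            for _ in range(n_inst)
        ]
        archs.append(FeatureArchitecture(pid, length, insts))
        family_of[pid] = None
        labels[pid] = _decoy_code(i)

    return Proteome(archs), family_of, labels


def write_synthetic_dataset(
    cfg: GeneratorConfig, outdir: str | Path
) -> Dict[str, Path]:
    """Generate and write the interchange TSV pair, clan table and labels.

    All outputs are deterministic under the config seed; re-running with
    the same config overwrites identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(cfg)
    proteome, family_of, labels = generate_proteome(cfg, catalog)
    paths = {
        "proteins": outdir / "proteins.tsv",
        "features": outdir / "features.tsv",
        "clans": outdir / "clans.tsv",
        "labels": outdir / "labels.tsv",
    }
    with paths["proteins"].open("w") as ps, paths["features"].open("w") as fs:
        write_architecture_tables(proteome, ps, fs)
    with paths["clans"].open("w") as sink:
        sink.write("# pfam_accession\tclan\n")
        for feature_id, clan in sorted(catalog.items()):
            sink.write(f"{feature_id.partition(':')[2]}\t{clan}\n")
    with paths["labels"].open("w") as sink:
        sink.write("# protein_id\tlabel\n")
        for pid in sorted(labels):
            sink.write(f"{pid}\t{labels[pid]}\n")
    return paths
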