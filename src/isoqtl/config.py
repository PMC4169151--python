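"""Pipeline configuration: a single YAML file driving every stage.

The file round-trips losslessly through :func:`load_config` /
:func:`save_config`; each stage reads only its own section.  Every run
writes a manifest (config hash, seed, package versions) next to its
outputs so results are auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import (ChromosomeSpec, FamilySpec, GenomeSpec, QtlSpec,
                       Scenario, demo_scenario)


@dataclass(frozen=True)
class EncodingParams:
    max_missing: float = 0.05
    collapse_bp: int = 64
    min_gap_mb: float = 10.0


@dataclass(frozen=True)
class MappingParams:
    alpha: float = 0.01
    n_perm: int = 1000
    max_steps: int = 10
    select_by: str = "fstat"
    threshold_per_step: bool = False
    subsets: tuple = ("AB", "ABC", "ABCD", "ABCDE")
    traits: tuple = ("FL", "HT")


@dataclass(frozen=True)
class PipelineConfig:
    scenario: Scenario
    encoding: EncodingParams = field(default_factory=EncodingParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    seed: int = 0
    outdir: str = "isoqtl_run"


# ---------------------------------------------------------------------------
# (De)serialization
# ---------------------------------------------------------------------------

def _scenario_to_dict(s: Scenario) -> dict:
    return {
        "chromosomes": [
            {"name": c.name, "length_bp": int(c.length_bp),
             "length_morgan": float(c.length_morgan),
             "map_points": [[int(b), float(m)] for b, m in c.map_points]}
            for c in s.genome.chromosomes
        ],
        "markers": {c: [int(p) for p in pos] for c, pos in s.genome.markers.items()},
        "families": [
            {"name": f.name, "n_lines": int(f.n_lines),
             "isogenicity": f.isogenicity,
             "segments": [[c, int(a), int(b)] for c, a, b in f.segments],
             "density": float(f.density)}
            for f in s.families
        ],
        "qtl": [
            {"name": q.name, "chrom": q.chrom, "pos_bp": int(q.pos_bp),
             "trait": q.trait, "a": {k: float(v) for k, v in q.a.items()},
             "d": {k: float(v) for k, v in q.d.items()},
             "censor_trigger": bool(q.censor_trigger)}
            for q in s.qtl
        ],
        "offsets": {t: {k: float(v) for k, v in d.items()}
                    for t, d in s.offsets.items()},
        "noise_sd": {t: float(v) for t, v in s.noise_sd.items()},
        "censor_trait": s.censor_trait,
        "censor_bound": float(s.censor_bound),
        "gbs_missing_rate": float(s.gbs_missing_rate),
        "n_high_missing_snps": int(s.n_high_missing_snps),
        "high_missing_rate": float(s.high_missing_rate),
        "bg_alt_freq": float(s.bg_alt_freq),
    }


def _scenario_from_dict(d: dict) -> Scenario:
    genome = GenomeSpec(
        tuple(ChromosomeSpec(c["name"], c["length_bp"], c["length_morgan"],
                             tuple((b, m) for b, m in c.get("map_points", ())))
              for c in d["chromosomes"]),
        {c: np.asarray(pos, dtype=np.int64) for c, pos in d["markers"].items()},
    )
    families = tuple(
        FamilySpec(f["name"], f["n_lines"], f["isogenicity"],
                   tuple((c, a, b) for c, a, b in f.get("segments", ())),
                   f.get("density", 0.0))
        for f in d["families"]
    )
    qtl = tuple(
        QtlSpec(q["name"], q["chrom"], q["pos_bp"], q["trait"],
                dict(q.get("a", {})), dict(q.get("d", {})),
                bool(q.get("censor_trigger", False)))
        for q in d.get("qtl", ())
    )
    return Scenario(genome, families, qtl, d["offsets"], d["noise_sd"],
                    d.get("censor_trait", ""), d.get("censor_bound", 138.0),
                    d.get("gbs_missing_rate", 0.0),
                    d.get("n_high_missing_snps", 0),
                    d.get("high_missing_rate", 0.3),
                    d.get("bg_alt_freq", 0.3))


def config_to_dict(cfg: PipelineConfig) -> dict:
    enc = asdict(cfg.encoding)
    mp = asdict(cfg.mapping)
    mp["subsets"] = list(mp["subsets"])
    mp["traits"] = list(mp["traits"])
    return {"scenario": _scenario_to_dict(cfg.scenario), "encoding": enc,
            "mapping": mp, "seed": int(cfg.seed), "outdir": cfg.outdir}


def config_from_dict(d: dict) -> PipelineConfig:
    if d.get("scenario") == "demo":
        scenario = demo_scenario()
    else:
        scenario = _scenario_from_dict(d["scenario"])
    enc = EncodingParams(**d.get("encoding", {}))
    md = dict(d.get("mapping", {}))
    md["subsets"] = tuple(md.get("subsets", MappingParams.subsets))
    md["traits"] = tuple(md.get("traits", MappingParams.traits))
    return PipelineConfig(scenario, enc, MappingParams(**md),
                          d.get("seed", 0), d.get("outdir", "isoqtl_run"))


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(outdir, cfg: PipelineConfig | None, seed: int) -> Path:
    import pandas
    import scipy

    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config_sha256": config_hash(cfg) if cfg is not None else "",
        "versions": {"isoqtl": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pandas.__version__},
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path
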