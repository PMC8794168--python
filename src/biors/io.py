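"""File formats: FASTA genomes, YAML consensus/layout specs, experiment
configs, and config hashing for output provenance.

FASTA is the only sequence format (chromosomes have no quality
semantics); T is normalized to U on read and U is always written.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .consensus import AlternativeConsensusSpec, ConsensusSpec, LayoutSpec
from .engines import EngineConfig
from .experiments import ExperimentSpec
from .fixtures import Fixture, get_fixture

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_consensus_file",
    "dump_consensus_file",
    "load_experiment_config",
    "config_hash",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; sequences uppercased with T mapped to U."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 80) -> None:
    """Write (id, sequence) pairs wrapped at ``wrap`` columns."""
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(recs)


# ------------------------------------------------------------- spec files

def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")


def _parse_pairs(d: dict, where: str) -> dict:
    out = {}
    for pos, pair in d.items():
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ValueError(f"{where}[{pos}]: expected a [value, alternative] pair")
        out[int(pos)] = (str(pair[0]), str(pair[1]))
    return out


def load_consensus_file(path):
    """Load a consensus spec (+ optional layout) from YAML.

    Keys: ``core_length``, ``unique`` {pos: base}, ``two_valued``
    {pos: [preferred, alternative]} *or* ``structures`` {m1: {pos: [value,
    alternative]}, m2: {...}}, optional ``layout`` {n_domains, window,
    delta}. Returns ``(spec, layout_or_None)``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    _reject_unknown(doc, {"core_length", "unique", "two_valued", "structures", "layout"}, str(path))
    core_length = int(doc.get("core_length", 26))
    unique = {int(p): str(b) for p, b in (doc.get("unique") or {}).items()}
    layout = None
    if "layout" in doc:
        lay = doc["layout"]
        _reject_unknown(lay, {"n_domains", "window", "delta", "core_length"}, f"{path}:layout")
        layout = LayoutSpec(
            n_domains=int(lay["n_domains"]),
            window=int(lay["window"]),
            core_length=int(lay.get("core_length", core_length)),
            delta=int(lay.get("delta", 100)),
        )
    if "structures" in doc:
        if "two_valued" in doc:
            raise ValueError(f"{path}: give either two_valued or structures, not both")
        st = doc["structures"]
        _reject_unknown(st, {"m1", "m2"}, f"{path}:structures")
        spec = AlternativeConsensusSpec(
            core_length, unique,
            _parse_pairs(st.get("m1") or {}, "m1"),
            _parse_pairs(st.get("m2") or {}, "m2"),
        )
    else:
        spec = ConsensusSpec(core_length, unique,
                             _parse_pairs(doc.get("two_valued") or {}, "two_valued"))
    return spec, layout


def dump_consensus_file(spec, path, layout: LayoutSpec | None = None) -> None:
    doc: dict = {"core_length": spec.core_length,
                 "unique": {p: b for p, b in sorted(spec.unique.items())}}
    if isinstance(spec, AlternativeConsensusSpec):
        doc["structures"] = {
            "m1": {p: list(v) for p, v in sorted(spec.m1.items())},
            "m2": {p: list(v) for p, v in sorted(spec.m2.items())},
        }
    else:
        doc["two_valued"] = {p: list(v) for p, v in sorted(spec.two_valued.items())}
    if layout is not None:
        doc["layout"] = {"n_domains": layout.n_domains, "window": layout.window,
                         "core_length": layout.core_length, "delta": layout.delta}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------- experiment configs

_ENGINE_KEYS = {f for f in EngineConfig.__dataclass_fields__}
_CONFIG_KEYS = {"fixture", "mode", "engine", "replicates", "base_seed", "sweep"}
_FIXTURE_KEYS = {"name", "n_domains", "window"}


def load_experiment_config(source) -> ExperimentSpec:
    """Build an :class:`ExperimentSpec` from a YAML file path or dict.

    Schema: ``fixture`` (name, or {name, n_domains, window}), optional
    ``mode``, ``engine`` {EngineConfig fields}, ``replicates``,
    ``base_seed``, optional ``sweep`` {axis: [values...]}. Unknown keys
    anywhere are rejected.
    """
    if isinstance(source, dict):
        doc, where = dict(source), "<config>"
    else:
        where = str(source)
        with open(source) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{where}: expected a mapping at top level")
    _reject_unknown(doc, _CONFIG_KEYS, where)
    fx = doc.get("fixture", "ss_simple_4_10")
    if isinstance(fx, dict):
        _reject_unknown(fx, _FIXTURE_KEYS, f"{where}:fixture")
        fixture: str | Fixture = get_fixture(
            fx["name"], n_domains=fx.get("n_domains"), window=fx.get("window"))
    else:
        fixture = str(fx)
    engine_doc = doc.get("engine") or {}
    _reject_unknown(engine_doc, _ENGINE_KEYS, f"{where}:engine")
    engine = EngineConfig(**engine_doc)
    return ExperimentSpec(
        fixture=fixture,
        engine=engine,
        replicates=int(doc.get("replicates", 20)),
        base_seed=int(doc.get("base_seed", 0)),
        mode=doc.get("mode"),
        sweep_axes=doc.get("sweep") or {},
    )


def config_hash(source) -> str:
    """Short stable hash of a config mapping (or YAML file) for sidecars."""
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    canon = yaml.safe_dump(source, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
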