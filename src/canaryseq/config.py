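"""Structured run configuration: YAML files with CLI overrides.

Every stochastic component carries an explicit seed after parsing — absent
seeds are defaulted and echoed back — so a run can always be reproduced
from its configuration echo alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from canaryseq.inference import EngineConfig
from canaryseq.models import SubstitutionModel
from canaryseq.pipeline import PipelineConfig
from canaryseq.seqs import Alphabet

__all__ = ["RunConfig", "load_run_config", "model_from_dict", "engine_from_dict"]

_MODEL_BUILDERS = {
    "JC69": SubstitutionModel.jc69,
    "Poisson": SubstitutionModel.poisson,
    "LG": SubstitutionModel.lg,
}


def model_from_dict(data: dict | None) -> SubstitutionModel:
    """Build a substitution model from a config mapping.

    ``kind`` selects the model; ``gamma_shape`` / ``n_rate_categories``
    control rate variation. GTR additionally accepts ``state_freqs`` and
    ``exchangeabilities`` (defaults: uniform frequencies, equal rates —
    re-estimated from the data by the internal engine).
    """
    data = dict(data or {})
    kind = data.pop("kind", "JC69")
    gamma_shape = data.pop("gamma_shape", None)
    n_cat = data.pop("n_rate_categories", 4)
    if kind == "GTR":
        freqs = data.pop("state_freqs", (0.25,) * 4)
        exch = data.pop("exchangeabilities", (1.0,) * 6)
        if data:
            raise ValueError(f"unknown model keys: {sorted(data)}")
        return SubstitutionModel.gtr(freqs, exch, gamma_shape, n_cat)
    if kind not in _MODEL_BUILDERS:
        raise ValueError(f"unknown model kind {kind!r}")
    if data:
        raise ValueError(f"unknown model keys: {sorted(data)}")
    return _MODEL_BUILDERS[kind](gamma_shape, n_cat)


def engine_from_dict(data: dict | None) -> EngineConfig:
    data = dict(data or {})
    model = model_from_dict(data.pop("model", None))
    return EngineConfig(
        engine=data.pop("engine", "internal"),
        model=model,
        nni_max_rounds=int(data.pop("nni_max_rounds", 20)),
        seed=int(data.pop("seed", 0)),
        external_command_template=data.pop("external_command_template", None),
        saturation_ceiling=float(data.pop("saturation_ceiling", 5.0)),
        brlen_tol=float(data.pop("brlen_tol", 1e-3)),
        brlen_max_sweeps=int(data.pop("brlen_max_sweeps", 5)),
        estimate_gtr=bool(data.pop("estimate_gtr", True)),
    )


@dataclass(frozen=True)
class RunConfig:
    """Merged pipeline + engine + I/O configuration of a `canary run`."""

    alignment: str
    interest_ids: tuple[str, ...]
    pipeline: PipelineConfig
    format: str = "fasta"
    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    outdir: str = "canary_out"

    def echo(self) -> dict:
        out = self.pipeline.echo()
        out.update(
            alignment=self.alignment,
            format=self.format,
            alphabet=self.alphabet.value,
            outdir=self.outdir,
        )
        return out


def load_run_config(
    config_path: str | Path | None = None, **overrides
) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over the file.

    Recognized keys: alignment, format, alphabet, interest (list of ids or
    path to an id-per-line file), outdir, engine (mapping), comp (mapping
    with n_sims/seed/alpha), recompute_full, seed (sets every seed at
    once).
    """
    data: dict = {}
    if config_path is not None:
        with open(config_path) as handle:
            data = yaml.safe_load(handle) or {}
    for key, value in overrides.items():
        if value is not None:
            data[key] = value

    alignment = data.get("alignment")
    if not alignment:
        raise ValueError("configuration must name an alignment file")
    interest = data.get("interest")
    if interest is None:
        raise ValueError("configuration must designate sequences of interest")
    if isinstance(interest, (str, Path)):
        interest = [
            line.strip()
            for line in Path(interest).read_text().splitlines()
            if line.strip()
        ]
    comp = dict(data.get("comp") or {})
    engine = engine_from_dict(data.get("engine"))
    master_seed = data.get("seed")
    if master_seed is not None:
        engine = replace(engine, seed=int(master_seed))
        comp.setdefault("seed", int(master_seed))
    pipeline = PipelineConfig(
        interest_ids=tuple(interest),
        engine=engine,
        comp_n_sims=int(comp.get("n_sims", 99)),
        comp_seed=int(comp.get("seed", 0)),
        comp_alpha=float(comp.get("alpha", 0.05)),
        recompute_full=bool(data.get("recompute_full", False)),
    )
    return RunConfig(
        alignment=str(alignment),
        interest_ids=tuple(interest),
        pipeline=pipeline,
        format=data.get("format", "fasta"),
        alphabet=Alphabet(data.get("alphabet", "nucleotide")),
        outdir=str(data.get("outdir", "canary_out")),
    )
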