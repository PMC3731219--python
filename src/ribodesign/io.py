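"""Readers and writers: FASTA, Vienna dot-bracket text, run configuration."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy_model import DotBracketStructure, NucleotideSequence
from .errors import SpecError, StructureError
from .gates import GateSpec, gate_from_dict, gate_to_dict
from .objective import ObjectiveConfig
from .optimizer import OptimizerConfig


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read FASTA records as RNA; T is normalized to U with a warning."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if "T" in residues:
            warnings.warn(
                f"{rec.id}: DNA alphabet detected, converting T -> U",
                stacklevel=2,
            )
            residues = residues.replace("T", "U")
        out.append(NucleotideSequence(rec.id, residues))
    return out


def write_fasta(path: str | Path, seqs: list[NucleotideSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_structure(
    path: str | Path,
) -> tuple[str | None, DotBracketStructure, float | None]:
    """Read a Vienna dot-bracket record: optional sequence line, structure
    line, optional trailing energy in parentheses.  '&' separates strands."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(">")
    ]
    if not lines:
        raise StructureError(f"{path}: no structure line")
    sequence = None
    struct_line = lines[0]
    if set(struct_line.replace("&", "")) <= set("ACGUT"):
        sequence = struct_line.replace("T", "U")
        if len(lines) < 2:
            raise StructureError(f"{path}: sequence without structure line")
        struct_line = lines[1]
    energy = None
    if struct_line.endswith(")") and " (" in struct_line:
        struct_line, _, tail = struct_line.rpartition(" (")
        try:
            energy = float(tail.rstrip(")"))
        except ValueError:
            raise StructureError(f"{path}: malformed energy field") from None
    structure = DotBracketStructure(struct_line.strip())
    if sequence is not None and len(sequence) != len(structure.symbols):
        raise StructureError(f"{path}: sequence/structure length mismatch")
    return sequence, structure, energy


def write_structure(
    path: str | Path,
    structure: DotBracketStructure,
    sequence: str | None = None,
    energy: float | None = None,
) -> None:
    lines = []
    if sequence is not None:
        lines.append(sequence)
    line = structure.symbols
    if energy is not None:
        line += f" ({energy:.2f})"
    lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Objective + optimizer + engine settings; round-trips through YAML."""

    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    engine: str = "reference"
    output_prefix: str = "design"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        data = {
            "objective": asdict(self.objective),
            "optimizer": asdict(self.optimizer),
            "engine": self.engine,
            "output_prefix": self.output_prefix,
            "log_level": self.log_level,
        }
        data["optimizer"]["word_schedule"] = [
            list(pair) for pair in self.optimizer.word_schedule
        ]
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"objective", "optimizer", "engine", "output_prefix",
                 "log_level"}
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown config keys: {sorted(unknown)}")

        def build(dc_type, section):
            fields = {f for f in dc_type.__dataclass_fields__}
            extra = set(section) - fields
            if extra:
                raise SpecError(
                    f"unknown {dc_type.__name__} keys: {sorted(extra)}"
                )
            return dc_type(**section)

        opt = dict(data.get("optimizer", {}))
        if "word_schedule" in opt:
            opt["word_schedule"] = tuple(
                (float(a), int(b)) for a, b in opt["word_schedule"]
            )
        return cls(
            objective=build(ObjectiveConfig, dict(data.get("objective", {}))),
            optimizer=build(OptimizerConfig, opt),
            engine=data.get("engine", "reference"),
            output_prefix=data.get("output_prefix", "design"),
            log_level=data.get("log_level", "INFO"),
        )


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(path: str | Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def read_gate(path: str | Path) -> GateSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SpecError(f"{path}: not a gate specification file")
    return gate_from_dict(data)


def write_gate(path: str | Path, gate: GateSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gate_to_dict(gate), fh, sort_keys=False)
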