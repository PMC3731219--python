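"""Adapter to the ViennaRNA nearest-neighbour folding engine.

Satisfies the same fold/cofold surface as the reference additive model but
delegates to the Turner-parameter dynamic programs of the ViennaRNA python
bindings.  Use it for realistically parameterized designs; the reference
model remains the exhaustively verifiable default.  Three-strand complexes
are not supported by RNAcofold and raise a capability error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .energy_model import DotBracketStructure, FoldResult, NucleotideSequence
from .errors import CapabilityError

try:
    import RNA  # noqa: N811 - ViennaRNA's module name

    HAVE_VIENNA = True
except ImportError:  # pragma: no cover - bindings present in supported envs
    RNA = None
    HAVE_VIENNA = False


def _require() -> None:
    if not HAVE_VIENNA:
        raise CapabilityError(
            "ViennaRNA python bindings are not installed; "
            "use the reference engine instead"
        )


@dataclass(frozen=True)
class ViennaEnergyModel:
    """Folding engine backed by ViennaRNA (Turner parameters, 37 C)."""

    model_id: str = "viennarna-turner"

    def fold(self, seq: NucleotideSequence) -> FoldResult:
        _require()
        db, energy = RNA.fold(seq.residues)
        return FoldResult(
            DotBracketStructure(db), float(energy), self.model_id, (seq,)
        )

    def cofold(self, seqs: Sequence[NucleotideSequence]) -> FoldResult:
        _require()
        if len(seqs) != 2:
            raise CapabilityError(
                "the ViennaRNA adapter supports exactly 2 strands"
            )
        joined = "&".join(s.residues for s in seqs)
        db, energy = RNA.cofold(joined)
        cut = len(seqs[0])
        symbols = db[:cut] + "&" + db[cut:]
        return FoldResult(
            DotBracketStructure(symbols), float(energy), self.model_id,
            tuple(seqs),
        )

    def delta_g_mfe(
        self, seq_a: NucleotideSequence, seq_b: NucleotideSequence
    ) -> float:
        """Formation free energy from Turner-parameter MFE endpoints."""
        dg = (
            self.cofold([seq_a, seq_b]).free_energy
            - self.fold(seq_a).free_energy
            - self.fold(seq_b).free_energy
        )
        return min(dg, 0.0)
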