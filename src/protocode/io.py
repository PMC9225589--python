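"""FASTA reading/writing and deterministic fixture generation.

FASTA parsing goes through Biopython; records are exposed as plain
``(identifier, sequence)`` tuples, where the identifier is the full header
text after ``>``.  Sequences are passed through as read — validation is
the consumer's job (the codec and translator enforce alphabets).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .assembly import assemble_strands
from .simulate import SimConfig, run_stage
from .tables import Stage

__all__ = ["read_fasta", "write_fasta", "generate_fixture"]

FIXTURE_KINDS = ("strands", "numeric-strands", "trace")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a standard (wrapped or unwrapped) FASTA file into ordered
    ``(identifier, sequence)`` tuples.

    An empty file is an explicit error, not an empty list.
    """
    with open(path) as handle:
        records = list(SimpleFastaParser(handle))
    if not records:
        raise ValueError(f"empty FASTA input: {path}")
    return records


def write_fasta(
    records: Sequence[tuple[str, str]],
    path: str | Path,
    line_width: int = 60,
) -> None:
    """Write ``(identifier, sequence)`` records as standard FASTA.

    ``line_width=0`` writes each sequence on a single line.
    """
    if not records:
        raise ValueError("no records to write")
    with open(path, "w") as handle:
        for identifier, seq in records:
            handle.write(f">{identifier}\n")
            if line_width <= 0:
                handle.write(seq + "\n")
            else:
                for i in range(0, max(len(seq), 1), line_width):
                    handle.write(seq[i : i + line_width] + "\n")


def generate_fixture(
    kind: str,
    stage: Stage | str,
    n: int,
    seed: int,
    out_dir: str | Path = ".",
) -> Path:
    """Write a deterministic test fixture and return its path.

    Kinds: ``strands`` (letter FASTA), ``numeric-strands`` (digit FASTA),
    ``trace`` (JSON of a noiseless stage run, GNC only without a chained
    bank).  Every fixture embeds its generating parameters in the record
    headers or JSON metadata, so a fixture is self-describing and
    byte-reproducible from them.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}, got {kind!r}")
    stage = Stage.coerce(stage)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{kind}_{stage.value.lower()}_n{n}_seed{seed}"
    if kind in ("strands", "numeric-strands"):
        strands = assemble_strands(stage, n, rng=seed)
        numeric = kind == "numeric-strands"
        records = [
            (
                f"{tag}_{i:03d} stage={stage.value} seed={seed} "
                f"length_nt={s.length_nt}",
                s.numeric if numeric else s.letters,
            )
            for i, s in enumerate(strands)
        ]
        path = out_dir / f"{tag}.fasta"
        write_fasta(records, path)
        return path
    if stage is not Stage.GNC:
        raise ValueError("trace fixtures run the first (GNC) stage only")
    config = SimConfig(stage=stage, max_cycles=max(n, 1000), seed=seed)
    bank, trace = run_stage(config)
    path = out_dir / f"{tag}.json"
    payload = {
        "metadata": {"kind": kind, "stage": stage.value, "n": n, "seed": seed},
        "converged": trace.converged,
        "cycles": trace.cycles,
        "mischarges": trace.mischarges,
        "events": [list(e) for e in trace.events],
        "initial_state": trace.initial_state,
        "final_state": trace.final_state,
        "counts": bank.counts,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
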