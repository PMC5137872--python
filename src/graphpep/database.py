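"""Target + decoy search database construction.

Peptide decoys reverse the sequence while keeping a C-terminal K/R in place
(so decoys remain fully tryptic); protein decoys are plain reversals.  A
decoy that collides with some target sequence would silently inflate the
target count, so collisions are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DECOY_PREFIX = "DECOY_"

__all__ = [
    "DECOY_PREFIX",
    "DbRecord",
    "DbReport",
    "decoy_peptide",
    "decoy_protein",
    "build_target_decoy_db",
    "write_fasta",
]


@dataclass
class DbRecord:
    id: str
    seq: str
    is_decoy: bool = False
    provenance: str = ""


@dataclass
class DbReport:
    n_targets: int = 0
    n_decoys: int = 0
    n_collisions: int = 0
    collided_ids: list[str] = field(default_factory=list)


def decoy_peptide(pep: str) -> str:
    """Reverse a peptide, preserving a C-terminal K/R."""
    if not pep:
        raise ValueError("empty peptide")
    if pep[-1] in "KR":
        return pep[-2::-1] + pep[-1]
    return pep[::-1]


def decoy_protein(prot: str) -> str:
    """Full reversal."""
    if not prot:
        raise ValueError("empty protein")
    return prot[::-1]


def build_target_decoy_db(
    targets: list[DbRecord], mode: str = "peptide"
) -> tuple[list[DbRecord], DbReport]:
    """Deduplicate targets by sequence and add one decoy per unique target.

    ``mode`` selects the decoy rule: ``peptide`` (reversal preserving the
    C-terminal K/R) or ``protein`` (full reversal).  Decoys identical to any
    target sequence are dropped and counted in the report.
    """
    if not targets:
        raise ValueError("empty target list")
    if mode not in ("peptide", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    make_decoy = decoy_peptide if mode == "peptide" else decoy_protein

    uniq: dict[str, DbRecord] = {}
    for t in targets:
        if not t.seq:
            raise ValueError(f"empty sequence for target {t.id!r}")
        if t.seq in uniq:
            prev = uniq[t.seq]
            merged = ";".join(p for p in (prev.provenance, t.provenance) if p)
            prev.provenance = merged
        else:
            uniq[t.seq] = DbRecord(t.id, t.seq, False, t.provenance)

    target_seqs = set(uniq)
    report = DbReport(n_targets=len(uniq))
    out = list(uniq.values())
    decoys = []
    for t in out:
        d = make_decoy(t.seq)
        if d in target_seqs:
            report.n_collisions += 1
            report.collided_ids.append(t.id)
            continue
        decoys.append(DbRecord(DECOY_PREFIX + t.id, d, True, f"decoy_of:{t.id}"))
    report.n_decoys = len(decoys)
    return out + decoys, report


def write_fasta(records: list[DbRecord], path, width: int = 80) -> None:
    """Deterministic FASTA writer (targets then decoys, each sorted by id)."""
    ordered = sorted(records, key=lambda r: (r.is_decoy, r.id))
    with open(path, "w") as fh:
        for r in ordered:
            desc = f" {r.provenance}" if r.provenance else ""
            fh.write(f">{r.id}{desc}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")
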