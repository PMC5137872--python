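"""PSM table parsing and target-decoy FDR estimation.

The estimator at rank *i* of the best-to-worst ordering is
``FDR_i = D_i / T_i`` (decoys over targets among the top *i*; 0 while no
target has been seen), and the q-value is the running minimum of the
estimate from the worst rank upward — the minimum FDR at which a match
would be accepted.  Peptide-level estimation keeps each stripped peptide's
best PSM and reruns the same procedure on the representatives.

The pipeline uses two thresholds: a permissive 5% peptide-level cut after
the first (peptide database) search, so that protein reconstruction sees a
broad peptide set, and a standard 1% cut on the second (protein database)
search for reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .database import DECOY_PREFIX

__all__ = [
    "PSMRecord",
    "parse_psm_table",
    "compute_qvalues",
    "filter_at_fdr",
    "summarize",
    "msgfplus_recommended_params",
]

# "+15.995" / "-17.03" style in-sequence mass annotations, and bracketed mods
_MOD_RE = re.compile(r"[+-][0-9.]+|\[[^\]]*\]|\([^)]*\)")
_FLANK_RE = re.compile(r"^(?:[A-Z-]|-)\.(.*)\.(?:[A-Z-]|-)$")


@dataclass
class PSMRecord:
    spectrum_id: str
    peptide: str            # stripped amino-acid sequence
    raw_peptide: str        # as written by the search engine
    protein_ids: list[str]
    score: float            # lower is better (E-value-like) unless stated
    is_decoy: bool
    q_psm: float | None = None
    q_peptide: float | None = None
    extras: dict = field(default_factory=dict)


def strip_peptide(raw: str) -> str:
    """Drop flanking residues (``K.PEPTIDER.S``) and mass annotations."""
    m = _FLANK_RE.match(raw)
    if m:
        raw = m.group(1)
    return _MOD_RE.sub("", raw)


_DIALECTS = {
    "msgfplus_tsv": {"spectrum": "SpecID", "peptide": "Peptide", "protein": "Protein", "score": "SpecEValue"},
    "generic_tsv": {"spectrum": "spectrum_id", "peptide": "peptide", "protein": "protein", "score": "score"},
}


def parse_psm_table(path, dialect: str = "msgfplus_tsv", decoy_prefix: str = DECOY_PREFIX) -> list[PSMRecord]:
    """Read a search-engine PSM table into records.

    A PSM is a decoy only when *all* its proteins carry the decoy prefix
    (matching both a target and a decoy counts as target).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            score = float(row[cols["score"]])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: unparseable score {row[cols['score']]!r} at row {idx}") from None
        prots = [p.strip() for p in re.split(r"[;,]", str(row[cols["protein"]])) if p.strip()]
        raw = str(row[cols["peptide"]])
        records.append(
            PSMRecord(
                spectrum_id=str(row[cols["spectrum"]]),
                peptide=strip_peptide(raw),
                raw_peptide=raw,
                protein_ids=prots,
                score=score,
                is_decoy=bool(prots) and all(p.startswith(decoy_prefix) for p in prots),
            )
        )
    return records


def _sort_key(r: PSMRecord, lower_is_better: bool, decoy_last: bool):
    s = r.score if lower_is_better else -r.score
    return (s, r.is_decoy if decoy_last else not r.is_decoy, r.spectrum_id, r.peptide)


def compute_qvalues(
    psms: list[PSMRecord],
    level: str = "psm",
    lower_is_better: bool = True,
    decoy_last_on_ties: bool = True,
    plus_one: bool = False,
) -> list[PSMRecord]:
    """Annotate q-values at PSM or peptide level; returns the input list.

    ``plus_one`` switches to the conservative (D+1)/T estimator.
    """
    if not psms:
        raise ValueError("no PSMs")
    if level not in ("psm", "peptide"):
        raise ValueError(f"unknown level {level!r}")

    if level == "peptide":
        best: dict[str, PSMRecord] = {}
        for r in sorted(psms, key=lambda r: _sort_key(r, lower_is_better, decoy_last_on_ties)):
            best.setdefault(r.peptide, r)
        reps = list(best.values())
    else:
        reps = list(psms)

    reps.sort(key=lambda r: _sort_key(r, lower_is_better, decoy_last_on_ties))
    n_d = n_t = 0
    fdr = []
    for r in reps:
        if r.is_decoy:
            n_d += 1
        else:
            n_t += 1
        num = n_d + (1 if plus_one else 0)
        fdr.append(num / n_t if n_t else 0.0)
    q = [0.0] * len(reps)
    running = float("inf")
    for i in range(len(reps) - 1, -1, -1):
        running = min(running, fdr[i])
        q[i] = running
    for r, qi in zip(reps, q):
        if level == "psm":
            r.q_psm = qi
        else:
            r.q_peptide = qi
    if level == "peptide":
        # propagate the representative's q to every PSM of the same peptide
        by_pep = {r.peptide: r.q_peptide for r in reps}
        for r in psms:
            r.q_peptide = by_pep[r.peptide]
    return psms


def filter_at_fdr(psms: list[PSMRecord], alpha: float, level: str = "psm") -> list[PSMRecord]:
    """Target (non-decoy) records accepted at q <= alpha at the given level."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    attr = "q_psm" if level == "psm" else "q_peptide"
    if level not in ("psm", "peptide"):
        raise ValueError(f"unknown level {level!r}")
    out = []
    for r in psms:
        q = getattr(r, attr)
        if q is None:
            raise ValueError(f"q-values at level {level!r} not computed")
        if not r.is_decoy and q <= alpha:
            out.append(r)
    return out


def summarize(accepted: list[PSMRecord], total_spectra: int) -> dict:
    """PSM count, unique stripped peptides, and % of spectra identified."""
    spectra = {r.spectrum_id for r in accepted}
    return {
        "n_psms": len(accepted),
        "n_unique_peptides": len({r.peptide for r in accepted}),
        "pct_spectra_identified": 100.0 * len(spectra) / total_spectra if total_spectra else 0.0,
    }


def msgfplus_recommended_params() -> str:
    """Recommended MSGF+ settings for searching the generated databases."""
    return (
        "# MSGF+ parameter recommendation for graph-derived databases\n"
        "PrecursorMassTolerance=15ppm\n"
        "IsotopeErrorRange=-1,2\n"
        "InstrumentID=1  # high-resolution LTQ\n"
        "MinCharge=1\n"
        "MaxCharge=7\n"
        "NumMods=2\n"
        "StaticMod=C2H3N1O1, C, fix, any, Carbamidomethyl\n"
        "DynamicMod=O1, M, opt, any, Oxidation\n"
        "# peptide-mode databases: search fully tryptic, each record is one peptide\n"
        "EnzymeID=1  # trypsin\n"
        "NTT=2\n"
    )
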