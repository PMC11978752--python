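"""Protein sequences, C-terminal segment (CTS) extraction and descriptors.

Bacterial group-I chaperonins (GroEL homologues) carry a short, usually
glycine/methionine-rich tail after a highly conserved proline near the C
terminus (position 525 in E. coli GroEL, tail ``(GGM)4M``).  This module
extracts that tail, computes its grand average of hydropathy (GRAVY,
Kyte-Doolittle) and isoelectric point (Bjellqvist pKa set), and assigns one
of three composition classes: gly-met-rich, charged/His-rich, or
pattern-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

log = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BZX")
VALID_AA = STANDARD_AA | AMBIGUOUS_AA

GLY_MET_RICH = "gly_met_rich"
CHARGED_HIS_RICH = "charged_his_rich"
PATTERN_FREE = "pattern_free"
CLASS_LABELS = (GLY_MET_RICH, CHARGED_HIS_RICH, PATTERN_FREE)


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header or illegal residue)."""


class NoAnchorError(ValueError):
    """No anchoring proline in the C-terminal region of a sequence."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence; residues uppercase one-letter codes."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - VALID_AA
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue code(s) {sorted(bad)}"
            )

    @property
    def has_ambiguity(self) -> bool:
        return bool(set(self.residues) & AMBIGUOUS_AA)


@dataclass(frozen=True)
class CTSRecord:
    """An extracted C-terminal segment with its descriptors.

    ``anchor_pos`` is the 1-based position of the anchoring proline in the
    parent sequence; ``tail`` is everything after it.  ``gravy``/``pi`` are
    None when the tail carries ambiguity codes (excluded with a warning).
    """

    parent_id: str
    anchor_pos: int
    tail: str
    gravy: float | None
    pi: float | None
    class_label: str = field(default=PATTERN_FREE)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into SequenceRecords (order preserved).

    Raises :class:`FastaParseError` naming the offending line for headers
    that are not FASTA or residues outside the 20 standard codes plus
    B/Z/X.
    """
    records: list[SequenceRecord] = []
    # Validate alphabet line-by-line so errors carry line numbers;
    # Bio.SeqIO does the actual record splitting below.
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                saw_header = True
                if len(line) == 1:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                continue
            if not saw_header:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            bad = set(line.upper()) - VALID_AA
            if bad:
                raise FastaParseError(
                    f"line {lineno}: illegal residue code(s) {sorted(bad)}"
                )
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq).upper(),
            )
        )
    return records


def gravy(peptide: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Raises ValueError on ambiguity codes (B/Z/X) -- callers must resolve
    or drop those peptides.
    """
    if not peptide:
        raise ValueError("empty peptide")
    peptide = peptide.upper()
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in peptide")
    return sum(KYTE_DOOLITTLE[aa] for aa in peptide) / len(peptide)


def net_charge(peptide: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (Bjellqvist pKa set)."""
    return IsoelectricPoint(peptide.upper()).charge_at_pH(ph)


def isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero.

    Found by bisection on [0, 14]; the charge function is strictly
    decreasing in pH so the root exists and is unique.
    """
    if not peptide:
        raise ValueError("empty peptide")
    ip = IsoelectricPoint(peptide.upper())
    lo, hi = 0.0, 14.0
    if ip.charge_at_pH(lo) < 0:
        return lo
    if ip.charge_at_pH(hi) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ip.charge_at_pH(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_cts(
    tail: str,
    *,
    gm_fraction: float = 0.6,
    his_fraction: float = 0.25,
    charged_fraction: float = 0.4,
) -> str:
    """Assign a composition class to a tail.

    gly_met_rich if G+M make up >= ``gm_fraction`` of the tail and at least
    one M is present; charged_his_rich if His alone reaches
    ``his_fraction`` or D/E/K/R/H together reach ``charged_fraction``;
    pattern_free otherwise.  Thresholds are exposed because the three
    groups are defined by composition, not by a published boundary.
    """
    if len(tail) < 3:
        raise ValueError("tail too short to classify (< 3 residues)")
    tail = tail.upper()
    n = len(tail)
    gm = (tail.count("G") + tail.count("M")) / n
    his = tail.count("H") / n
    charged = sum(tail.count(aa) for aa in "DEKRH") / n
    if gm >= gm_fraction and "M" in tail:
        return GLY_MET_RICH
    if his >= his_fraction or charged >= charged_fraction:
        return CHARGED_HIS_RICH
    return PATTERN_FREE


def extract_cts(
    seq: SequenceRecord,
    anchor_hint: int | None = None,
    anchor_window: int = 40,
) -> CTSRecord:
    """Extract the CTS anchored at the conserved C-terminal proline.

    The anchor is the last proline within the C-terminal ``anchor_window``
    residues (so the tail is at most ``anchor_window - 1`` long).  When an
    alignment column hint is available (the proline aligned to GroEL
    position 525) pass it as ``anchor_hint`` (1-based) and it takes
    precedence, provided it is a proline.

    Raises :class:`NoAnchorError` when no proline lies in the C-terminal
    third of the sequence.
    """
    residues = seq.residues
    n = len(residues)
    if anchor_hint is not None:
        if not 1 <= anchor_hint <= n or residues[anchor_hint - 1] != "P":
            raise NoAnchorError(
                f"{seq.id}: anchor hint {anchor_hint} is not a proline"
            )
        anchor = anchor_hint
    else:
        start = max(0, n - anchor_window)
        idx = residues.rfind("P", start, n - 1)
        if idx < 0:
            raise NoAnchorError(
                f"{seq.id}: no proline in the C-terminal {anchor_window} residues"
            )
        anchor = idx + 1
    tail = residues[anchor:]
    if not tail:
        raise NoAnchorError(f"{seq.id}: anchoring proline is the last residue")
    if set(tail) & AMBIGUOUS_AA:
        log.warning(
            "%s: tail contains ambiguity codes; GRAVY/pI not computed", seq.id
        )
        g, p = None, None
    else:
        g = gravy(tail)
        p = isoelectric_point(tail)
        assert math.isfinite(g) and 0.0 < p < 14.0
    label = classify_cts(tail) if len(tail) >= 3 else PATTERN_FREE
    return CTSRecord(
        parent_id=seq.id,
        anchor_pos=anchor,
        tail=tail,
        gravy=g,
        pi=p,
        class_label=label,
    )


def scan_fasta(path, anchor_window: int = 40) -> list[CTSRecord]:
    """Extract CTSs for every sequence in a FASTA file; sequences without
    an anchor are logged and skipped."""
    out = []
    for rec in read_fasta(path):
        try:
            out.append(extract_cts(rec, anchor_window=anchor_window))
        except NoAnchorError as exc:
            log.warning("skipping %s: %s", rec.id, exc)
    return out
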