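"""Terminator-insulation scoring and integrase att-site off-target screening.

Two complementary assays quantify how well a terminator blocks RNA
polymerase:

* a two-reporter cytometry assay (GFP upstream, RFP downstream of the
  candidate terminator) yielding the terminator strength
  T_S = (<GFP>/<RFP>)_term / (<GFP>/<RFP>)_ref on autofluorescence-
  subtracted geometric means — T_S = 30 means 97% of transcription is
  blocked, and readthrough = 1/T_S;

* strand-specific RNA-seq coverage, where readthrough is estimated as the
  ratio of mean profile height in the 25-bp window directly downstream of
  the annotated terminator to the 25-bp window directly upstream (in the
  direction of transcription).

The coverage-based after/before ratio is a READTHROUGH (small = strong);
both the ratio and its reciprocal strength are reported so the two assays
share a scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 25
DEFAULT_PSEUDOCOUNT = 0.1  # normalized units; guards silent regions


@dataclass(frozen=True)
class TSMeasurement:
    strength: float  # T_S, fold-reduction across the terminator
    direction: str = "forward"  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("terminator strength must be > 0")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")

    @property
    def readthrough(self) -> float:
        return 1.0 / self.strength


@dataclass
class CoverageProfile:
    """Per-base normalized transcription profile of one strand of one
    replicon.  ``values[i]`` covers genome position i+1 (1-based)."""

    values: np.ndarray
    strand: str  # "sense" | "antisense"
    total_mapped_nt: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in ("sense", "antisense"):
            raise ValueError("strand must be 'sense' or 'antisense'")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TerminatorAnnotation:
    """1-based inclusive genome coordinates (GFF3 convention)."""

    id: str
    start: int
    end: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"{self.id}: require 1 <= start <= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")


_STRAND_OF = {"+": "sense", "-": "antisense"}


def ts_cytometry(
    gfp_term: float,
    rfp_term: float,
    gfp_ref: float,
    rfp_ref: float,
    autofluor_gfp: float = 0.0,
    autofluor_rfp: float = 0.0,
    direction: str = "forward",
) -> TSMeasurement:
    """Terminator strength from the two-reporter cytometry assay.

    All four inputs are geometric-mean fluorescences; the reference
    construct carries no terminator between the reporters.  Autofluorescence
    is subtracted from each channel before forming the ratio of ratios.
    """
    vals = {
        "gfp_term": gfp_term - autofluor_gfp,
        "rfp_term": rfp_term - autofluor_rfp,
        "gfp_ref": gfp_ref - autofluor_gfp,
        "rfp_ref": rfp_ref - autofluor_rfp,
    }
    for name, v in vals.items():
        if v <= 0:
            raise ValueError(f"{name}: nonpositive after autofluorescence subtraction")
    ts = (vals["gfp_term"] / vals["rfp_term"]) / (vals["gfp_ref"] / vals["rfp_ref"])
    return TSMeasurement(strength=ts, direction=direction)


def normalize_coverage(
    raw_counts, total_mapped_nt: int, strand: str = "sense"
) -> CoverageProfile:
    """Depth-normalize per-base read coverage: value = raw / total * 1e9."""
    if total_mapped_nt <= 0:
        raise ValueError("total_mapped_nt must be > 0")
    raw = np.asarray(raw_counts, dtype=float)
    return CoverageProfile(
        values=raw / total_mapped_nt * 1e9,
        strand=strand,
        total_mapped_nt=int(total_mapped_nt),
    )


def readthrough_ratio(
    profile: CoverageProfile,
    t: TerminatorAnnotation,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> TSMeasurement:
    """Estimate terminator readthrough from a coverage profile.

    readthrough = mean(window downstream of the terminator, in the
    direction of transcription) / mean(window upstream); both means get a
    small pseudocount.  The windows abut the annotated boundaries and do
    not overlap the terminator body.  Strength = 1/readthrough.
    """
    if _STRAND_OF[t.strand] != profile.strand:
        raise ValueError(
            f"{t.id}: terminator on {t.strand!r} strand does not match "
            f"{profile.strand} profile"
        )
    n = len(profile)
    lo = t.start - 1 - window  # 0-based start of the left window
    hi = t.end + window  # 0-based end (exclusive) of the right window
    if lo < 0 or hi > n:
        raise ValueError(f"{t.id}: {window}-bp window extends past the replicon edge")
    left = profile.values[t.start - 1 - window : t.start - 1]
    right = profile.values[t.end : t.end + window]
    if t.strand == "+":
        before, after = left, right
    else:
        before, after = right, left
    rt = (float(np.mean(after)) + pseudocount) / (float(np.mean(before)) + pseudocount)
    return TSMeasurement(strength=1.0 / rt, direction="forward")


def rank_terminators(
    profiles: "CoverageProfile | dict[str, CoverageProfile]",
    annotations: list[TerminatorAnnotation],
    exclude: set[str] | None = None,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Score every annotated terminator and rank by descending strength.

    ``profiles`` is either a single strand profile or a dict keyed by
    "sense"/"antisense".  Previously used terminators are removed via
    ``exclude``.  Ties keep annotation input order (stable sort).
    Returns a DataFrame with columns id, strand, readthrough, strength, rank.
    """
    if isinstance(profiles, CoverageProfile):
        profiles = {profiles.strand: profiles}
    exclude = exclude or set()
    rows = []
    for t in annotations:
        if t.id in exclude:
            continue
        prof = profiles.get(_STRAND_OF[t.strand])
        if prof is None:
            raise ValueError(
                f"{t.id}: no {_STRAND_OF[t.strand]}-strand profile supplied"
            )
        m = readthrough_ratio(prof, t, window=window, pseudocount=pseudocount)
        rows.append(
            {"id": t.id, "strand": t.strand, "readthrough": m.readthrough,
             "strength": m.strength}
        )
    df = pd.DataFrame(rows, columns=["id", "strand", "readthrough", "strength"])
    df = df.sort_values("strength", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def select_bidirectional(
    measurements: dict[str, tuple[TSMeasurement, TSMeasurement]],
    min_fwd: float = 105.0,
    min_rev: float = 25.0,
) -> list[str]:
    """Filter bidirectional double terminators suitable for flanking a
    landing pad: strictly T_S > min_fwd forward AND T_S > min_rev reverse.

    ``measurements`` maps terminator id -> (forward, reverse) measurement.
    Returns passing ids in input order.
    """
    passing = []
    for tid, pair in measurements.items():
        if len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError(f"{tid}: both directions must be measured")
        fwd, rev = pair
        if fwd.strength > min_fwd and rev.strength > min_rev:
            passing.append(tid)
    return passing


# ---------------------------------------------------------------------------
# att-site off-target screening


@dataclass(frozen=True)
class ScreenConfig:
    """Rejection thresholds for the genomic off-target screen."""

    min_query_coverage: float = 0.30
    max_evalue: float = 0.1
    exact_seed_len: int = 28
    # Karlin-Altschul parameters for the +2/-3/-5/-2 scoring scheme
    # (blastn-like defaults)
    ka_lambda: float = 0.625
    ka_K: float = 0.41

    def __post_init__(self) -> None:
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


@dataclass(frozen=True)
class ScreenResult:
    accept: bool
    reasons: tuple[str, ...]  # subset of {"exact_match", "query_coverage", "evalue"}
    best_score: float
    best_coverage: float
    best_evalue: float


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, name: str) -> str:
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name}: ambiguous or non-ACGT bases present")
    return seq


def _has_exact_seed(att: str, genome: str, k: int) -> bool:
    kmers = {genome[i : i + k] for i in range(len(genome) - k + 1)}
    return any(att[i : i + k] in kmers for i in range(len(att) - k + 1))


def _best_local_alignment(att: str, genome: str):
    """Smith-Waterman with blastn-like scoring (+2 match, -3 mismatch,
    -5 gap open, -2 gap extend) on both strands; returns (score,
    query_coverage)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    best_score, best_cov = 0.0, 0.0
    for target in (genome, _revcomp(genome)):
        score = aligner.score(target, att)
        if score > best_score:
            aln = aligner.align(target, att)[0]
            qspan = aln.aligned[1]
            covered = sum(int(e - s) for s, e in qspan)
            best_score = float(score)
            best_cov = covered / len(att)
    return best_score, best_cov


def screen_att_offtarget(
    att: str, genome: str, cfg: ScreenConfig = ScreenConfig()
) -> ScreenResult:
    """Screen a phage-integrase att site against a genome for off-targets.

    The site is REJECTED if any of three criteria fire:
    (i)   an exact shared substring of >= ``exact_seed_len`` bases on either
          strand (surrogate for a megablast hit);
    (ii)  the best local alignment covers more than ``min_query_coverage``
          of the att site;
    (iii) the best local alignment is statistically significant
          (Karlin-Altschul E-value below ``max_evalue``).
    Acceptance means the att site has no credible genomic match and is safe
    to use for targeted integration.
    """
    att = _check_alphabet(att, "att")
    genome = _check_alphabet(genome, "genome")
    if len(att) < cfg.exact_seed_len:
        raise ValueError("att site shorter than the exact-match seed length")

    reasons = []
    if _has_exact_seed(att, genome, cfg.exact_seed_len) or _has_exact_seed(
        _revcomp(att), genome, cfg.exact_seed_len
    ):
        reasons.append("exact_match")

    score, coverage = _best_local_alignment(att, genome)
    # E = K * m * n * exp(-lambda * S); search space doubled for two strands
    evalue = cfg.ka_K * len(att) * (2 * len(genome)) * math.exp(-cfg.ka_lambda * score)
    if coverage > cfg.min_query_coverage:
        reasons.append("query_coverage")
    if evalue < cfg.max_evalue:
        reasons.append("evalue")

    return ScreenResult(
        accept=not reasons,
        reasons=tuple(reasons),
        best_score=score,
        best_coverage=coverage,
        best_evalue=evalue,
    )


# ---------------------------------------------------------------------------
# file I/O (bedGraph / fixed-step WIG / GFF3)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences (e.g. a genome and att sites) from FASTA."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bedgraph(path: str | Path, replicon_len: int, strand: str) -> CoverageProfile:
    """Read a single-replicon bedGraph (0-based half-open intervals) into a
    dense per-base profile."""
    values = np.zeros(replicon_len, dtype=float)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    for _, row in df.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if s < 0 or e > replicon_len or s >= e:
            raise ValueError(f"bedGraph interval [{s}, {e}) out of range")
        values[s:e] = float(row["value"])
    return CoverageProfile(values=values, strand=strand)


def write_bedgraph(
    profile: CoverageProfile, path: str | Path, chrom: str = "replicon"
) -> None:
    """Write a dense profile as run-length-encoded bedGraph."""
    vals = profile.values
    with open(path, "w", encoding="utf-8") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                fh.write(f"{chrom}\t{start}\t{i}\t{vals[start]:g}\n")
                start = i


def read_gff3_terminators(path: str | Path) -> list[TerminatorAnnotation]:
    """Read terminator annotations from a GFF3 file (all feature rows)."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    out = []
    for i, row in df.iterrows():
        attrs = dict(
            kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
        )
        out.append(
            TerminatorAnnotation(
                id=attrs.get("ID", f"feature{i + 1}"),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
            )
        )
    return out


def write_gff3_terminators(
    annotations: list[TerminatorAnnotation], path: str | Path, chrom: str = "replicon"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for t in annotations:
            fh.write(
                f"{chrom}\trnie\tterminator\t{t.start}\t{t.end}\t.\t{t.strand}\t.\tID={t.id}\n"
            )
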