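"""Targeted-therapy status extraction and exact association testing.

Per-patient PARP-inhibitor status is assembled from heterogeneous sources:
*discussion* comes from Information-topic sentences that mention a lexicon
term (generic names, brand names, PARP/PARPi abbreviations); *prescription*
comes from a structured medication table, clinical-data-management report
lines, or a "Current Medications" note section.  A prescription implies a
discussion in the three-way status (none / discussion only / discussion plus
prescription).

The association between mutation status (Mutated / VUS / Negative) and
therapy status is tested with Fisher's exact test for general r x c tables:
the two-sided p-value sums the hypergeometric probabilities, over all tables
with the observed margins, of every table no more probable than the observed
one.  Enumeration is exact up to a configurable workload bound, beyond which
a seeded Monte-Carlo estimate over margin-preserving permutations is used.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .textprep import SentenceRecord

logger = logging.getLogger(__name__)

MUTATION_LEVELS = ("Mutated", "VUS", "Negative")
THERAPY_LEVELS = ("none", "discussion_only", "discussion_plus_prescription")


@dataclass
class TherapyLexicon:
    generic: list[str] = field(default_factory=list)
    abbreviations: list[str] = field(default_factory=list)
    brands: list[str] = field(default_factory=list)
    current_medication_headers: list[str] = field(
        default_factory=lambda: ["current medications?"])

    @classmethod
    def default(cls) -> "TherapyLexicon":
        text = resources.files("rwegm.data").joinpath("therapy_lexicon.yaml").read_text()
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "TherapyLexicon":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def all_terms(self) -> list[str]:
        return list(self.generic) + list(self.abbreviations) + list(self.brands)

    def term_pattern(self) -> re.Pattern:
        alts = "|".join(re.escape(t) for t in
                        sorted(self.all_terms(), key=len, reverse=True))
        return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)

    def header_pattern(self) -> re.Pattern:
        alts = "|".join(self.current_medication_headers)
        return re.compile(rf"(?:{alts})\s*:?", re.IGNORECASE)


def extract_therapy_status(
    labeled_sentences: Iterable[tuple[SentenceRecord, str]],
    med_table: Optional[pd.DataFrame] = None,
    cdm_lines: Optional[Iterable[tuple[str, str]]] = None,
    lexicon: Optional[TherapyLexicon] = None,
) -> dict[str, str]:
    """Per-patient therapy status from notes, medication table and CDM lines.

    ``med_table`` needs columns patient_id and drug; ``cdm_lines`` is an
    iterable of (patient_id, line) pairs.  Matching is case-insensitive on
    word boundaries.  A lexicon hit inside a current-medications note section
    counts as a prescription regardless of the sentence's topic label.
    """
    lex = lexicon or TherapyLexicon.default()
    term_pat = lex.term_pattern()
    header_pat = lex.header_pattern()

    discussed: set[str] = set()
    prescribed: set[str] = set()
    for rec, label in labeled_sentences:
        if not term_pat.search(rec.raw_text):
            continue
        if header_pat.search(rec.raw_text):
            prescribed.add(rec.patient_id)
        elif label == "Information":
            discussed.add(rec.patient_id)
    if med_table is not None and len(med_table):
        for _, row in med_table.iterrows():
            if term_pat.search(str(row["drug"])):
                prescribed.add(str(row["patient_id"]))
    for pid, line in cdm_lines or []:
        if term_pat.search(line):
            prescribed.add(str(pid))

    only_rx = prescribed - discussed
    if only_rx:
        logger.warning(
            "%d patient(s) have a prescription without a discussion", len(only_rx))
    out: dict[str, str] = {}
    for pid in discussed | prescribed:
        out[pid] = ("discussion_plus_prescription" if pid in prescribed
                    else "discussion_only")
    return out


def contingency_table(
    mutation_status: Mapping[str, str],
    therapy_status: Mapping[str, str],
    row_levels: Sequence[str] = MUTATION_LEVELS,
    col_levels: Sequence[str] = THERAPY_LEVELS,
) -> pd.DataFrame:
    """Mutation-status x therapy-status patient counts (each patient once)."""
    table = pd.DataFrame(0, index=list(row_levels), columns=list(col_levels))
    for pid, mstat in mutation_status.items():
        tstat = therapy_status.get(pid, "none")
        table.loc[mstat, tstat] += 1
    return table


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str           # "exact" | "monte_carlo"
    n_tables: Optional[int] = None
    n_draws: Optional[int] = None


def _compositions(total: int, bounds: Sequence[int]):
    """All length-len(bounds) nonnegative integer tuples with the given sum
    and per-cell upper bounds."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    lo = max(0, total - sum(bounds[1:]))
    for x in range(lo, min(total, bounds[0]) + 1):
        for rest in _compositions(total - x, bounds[1:]):
            yield (x,) + rest


def _exact_workload(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Upper estimate of the enumeration grid size."""
    est = 1.0
    for r in row_sums[:-1]:
        est *= float(np.prod(np.minimum(col_sums[:-1], r) + 1))
    return est


def fisher_exact(
    table,
    rel_tol: float = 1e-7,
    max_workload: float = 5e7,
    n_mc: int = 1_000_000,
    seed: int = 0,
    method: str = "auto",
) -> FisherResult:
    """Two-sided Fisher exact p-value for an r x c count table.

    The probability-ordering criterion is used: p = sum of P(T) over tables T
    with the observed margins and P(T) <= P(observed) * (1 + rel_tol).
    Zero rows/columns are dropped with a warning.  ``method`` is "auto",
    "exact" or "mc"; auto switches to Monte Carlo when the enumeration
    workload estimate exceeds ``max_workload``.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of nonnegative counts")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping zero-margin rows/columns")
        obs = obs[keep_r][:, keep_c]
    n = int(obs.sum())
    if n == 0:
        raise ValueError("table total must be > 0")
    if obs.shape[0] == 1 or obs.shape[1] == 1:
        return FisherResult(p_value=1.0, method="exact", n_tables=1)
    if obs.shape[0] > obs.shape[1]:
        obs = obs.T  # fewer rows -> shallower recursion
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)

    lf = gammaln(np.arange(n + 1) + 1.0)  # log k!
    log_const = float(lf[row_sums].sum() + lf[col_sums].sum() - lf[n])
    log_p_obs = log_const - float(lf[obs].sum())
    cutoff = log_p_obs + math.log1p(rel_tol)

    if method == "exact" or (
        method == "auto" and _exact_workload(row_sums, col_sums) <= max_workload
    ):
        p, n_tables = _fisher_enumerate(row_sums, col_sums, lf, log_const, cutoff)
        return FisherResult(p_value=min(p, 1.0), method="exact", n_tables=n_tables)
    if method not in ("auto", "mc"):
        raise ValueError(f"unknown method {method!r}")
    p = _fisher_mc(obs, row_sums, col_sums, lf, log_const, cutoff, n_mc, seed)
    return FisherResult(p_value=p, method="monte_carlo", n_draws=n_mc)


def _fisher_enumerate(row_sums, col_sums, lf, log_const, cutoff):
    """DFS over rows; the final two rows are evaluated as a vectorized grid."""
    r, c = len(row_sums), len(col_sums)
    total_p = 0.0
    n_tables = 0

    def two_row(colsums: np.ndarray, ra: int, partial: float):
        nonlocal total_p, n_tables
        # grid over the first c-1 cells of the penultimate row
        axes = [np.arange(min(int(cs), ra) + 1) for cs in colsums[:-1]]
        grids = np.meshgrid(*axes, indexing="ij", sparse=False) if axes else []
        s = sum(grids) if grids else np.zeros(())
        last = ra - s
        ok = (last >= 0) & (last <= colsums[-1])
        term = np.zeros_like(s, dtype=float)
        for j, g in enumerate(grids):
            term += lf[g] + lf[colsums[j] - g]
        term = term + np.where(ok, lf[np.clip(last, 0, None)]
                               + lf[np.clip(colsums[-1] - last, 0, None)], 0.0)
        logp = partial - term
        valid = ok
        n_tables += int(valid.sum())
        sel = valid & (logp <= cutoff)
        if sel.any():
            total_p += float(np.exp(logp[sel]).sum())

    def rec(i: int, colsums: np.ndarray, partial: float):
        if i == r - 2:
            two_row(colsums, int(row_sums[i]), partial)
            return
        bounds = [min(int(cs), int(row_sums[i])) for cs in colsums]
        for comp in _compositions(int(row_sums[i]), bounds):
            rest = colsums - np.array(comp)
            # feasibility: remaining rows must be able to absorb remaining cols
            if rest.sum() != row_sums[i + 1:].sum():
                continue
            rec(i + 1, rest, partial - float(lf[list(comp)].sum()))

    rec(0, col_sums.copy(), log_const)
    return total_p, n_tables


def _fisher_mc(obs, row_sums, col_sums, lf, log_const, cutoff, n_mc, seed):
    """Monte-Carlo p-value: margin-preserving random tables via permutation."""
    r, c = obs.shape
    n = int(obs.sum())
    row_labels = np.repeat(np.arange(r), row_sums)
    col_labels = np.repeat(np.arange(c), col_sums)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 2000
    done = 0
    while done < n_mc:
        b = min(batch, n_mc - done)
        perm = rng.permuted(np.tile(col_labels, (b, 1)), axis=1)
        cells = row_labels[None, :] * c + perm
        offsets = (np.arange(b) * (r * c))[:, None]
        flat = np.bincount((cells + offsets).ravel(), minlength=b * r * c)
        tables = flat.reshape(b, r * c)
        logp = log_const - lf[tables].sum(axis=1)
        hits += int((logp <= cutoff).sum())
        done += b
    return (hits + 1) / (n_mc + 1)
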