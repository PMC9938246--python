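"""GWAS summary statistics: containers, validation, instrument selection, harmonisation.

Two-sample Mendelian randomisation consumes per-variant summary associations:
for each SNP an effect estimate on the exposure (here an iron biomarker, in
SD units of the rank-normalised trait) and on the outcome (sepsis, log-odds).
Before any estimation the two sides must be aligned so that both effects
refer to the same counted allele; variants are selected by a p-value
threshold and greedy LD clumping; missing outcome variants may be replaced
by LD proxies.

Every input SNP leaves :func:`harmonise` with an explicit ``action`` so the
full provenance of the instrument set is auditable — nothing is silently
dropped or silently kept.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the tab-separated summary-statistic format
SUMMARY_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: actions that leave a usable instrument behind
KEPT_ACTIONS = ("kept", "flipped", "proxy_substituted")

#: all recognised harmonisation actions
ACTIONS = KEPT_ACTIONS + ("dropped_palindromic", "dropped_missing", "dropped_incompatible")

#: conventional threshold below which an instrument is considered weak
WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """Raised when a per-SNP F statistic falls below the conventional threshold of 10."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with one trait.

    ``beta`` is per allele of ``effect_allele``: SD units for exposures,
    log-odds for binary outcomes.  ``eaf`` is the effect-allele frequency and
    may be missing (only needed to orient palindromic variants).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None
    note: str | None = None

    def problems(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        out: list[str] = []
        if not self.snp_id:
            out.append("empty snp_id")
        if not self.effect_allele or not self.other_allele:
            out.append("empty allele")
        elif self.effect_allele == self.other_allele:
            out.append("identical alleles")
        if not (math.isfinite(self.beta)):
            out.append("non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            out.append("se must be finite and > 0")
        if not (0 < self.pval <= 1):
            out.append("pval outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            out.append("eaf outside (0, 1)")
        return out

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class HarmonisedInstrument:
    """An exposure/outcome-aligned variant with its harmonisation action recorded."""

    snp_id: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float | None
    outcome_se: float | None
    action: str
    proxy_id: str | None = None
    proxy_r2: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown harmonisation action {self.action!r}")
        if self.action in KEPT_ACTIONS:
            if self.outcome_se is None or not self.outcome_se > 0:
                raise ValueError(f"{self.snp_id}: kept instrument needs outcome se > 0")
            if not self.exposure_se > 0:
                raise ValueError(f"{self.snp_id}: kept instrument needs exposure se > 0")

    @property
    def usable(self) -> bool:
        return self.action in KEPT_ACTIONS


@dataclass
class InstrumentSet:
    """A harmonised, analysis-ready instrument set for one biomarker."""

    biomarker_name: str
    instruments: list[HarmonisedInstrument]
    p_threshold: float = 5e-8
    r2_clump_threshold: float = 0.01
    per_snp_f: list[float] = field(default_factory=list)
    mean_f: float | None = None


@dataclass
class Selection:
    """Result of p-filtering + LD clumping, before outcome harmonisation."""

    snps: list[SnpAssociation]
    p_threshold: float
    r2_max: float
    ld_supplied: bool
    dropped: dict[str, str] = field(default_factory=dict)


def read_summary_table(path, column_map: Mapping[str, str] | None = None, sep: str = "\t") -> list[SnpAssociation]:
    """Read a delimited summary-statistic table into validated records.

    ``column_map`` maps canonical names (``snp``, ``effect_allele``, ...) to
    the file's actual column names.  Rows violating the record invariants are
    rejected with row-numbered diagnostics; accepted/rejected counts are
    logged.  Raises if a mandatory column is absent or no valid row remains.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    colmap = dict(column_map or {})
    mandatory = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
    for canon in SUMMARY_COLUMNS:
        name = colmap.get(canon, canon)
        if canon in mandatory and name not in df.columns:
            raise ValueError(f"missing mandatory column {name!r} in {path}")

    def col(canon, default=None):
        name = colmap.get(canon, canon)
        return df[name] if name in df.columns else pd.Series([default] * len(df))

    records: list[SnpAssociation] = []
    rejected: list[str] = []
    eafs, ns = col("eaf"), col("n")
    for i in range(len(df)):
        eaf = eafs.iloc[i]
        eaf = None if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) else float(eaf)
        n = ns.iloc[i]
        n = None if n is None or (isinstance(n, float) and math.isnan(n)) else int(n)
        rec = SnpAssociation(
            snp_id=str(col("snp").iloc[i]),
            effect_allele=str(col("effect_allele").iloc[i]).upper(),
            other_allele=str(col("other_allele").iloc[i]).upper(),
            eaf=eaf,
            beta=float(col("beta").iloc[i]),
            se=float(col("se").iloc[i]),
            pval=float(col("pval").iloc[i]),
            n=n,
        )
        probs = rec.problems()
        if probs:
            rejected.append(f"row {i + 2}: {'; '.join(probs)}")
        else:
            records.append(rec)
    logger.info("read %s: %d accepted, %d rejected", path, len(records), len(rejected))
    for msg in rejected:
        logger.warning("rejected %s", msg)
    if not records:
        raise ValueError(f"no valid summary rows in {path}: {rejected[:5]}")
    return records


def write_summary_table(assocs: Sequence[SnpAssociation], path) -> None:
    """Write records in the canonical tab-separated format (round-trips exactly)."""
    df = pd.DataFrame(
        {
            "snp": [a.snp_id for a in assocs],
            "effect_allele": [a.effect_allele for a in assocs],
            "other_allele": [a.other_allele for a in assocs],
            "eaf": [a.eaf for a in assocs],
            "beta": [a.beta for a in assocs],
            "se": [a.se for a in assocs],
            "pval": [a.pval for a in assocs],
            "n": [a.n for a in assocs],
        }
    )
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _r2_lookup(ld, a: str, b: str) -> float:
    if isinstance(ld, pd.DataFrame):
        if a in ld.index and b in ld.columns:
            return float(ld.at[a, b])
        return 0.0
    # mapping of frozenset / tuple pairs
    return float(ld.get((a, b), ld.get((b, a), 0.0)))


def select_instruments(
    assocs: Sequence[SnpAssociation],
    p_threshold: float = 5e-8,
    ld_r2=None,
    r2_max: float = 0.01,
) -> Selection:
    """p-filter then greedily LD-clump exposure associations.

    Survivors of the strict ``p < p_threshold`` filter are sorted by ascending
    p (ties broken lexicographically on snp_id); the best is kept and every
    remaining SNP with r2 >= ``r2_max`` against it is discarded, repeatedly.
    Without an LD matrix only the p-filter applies, flagged via
    ``ld_supplied=False``.
    """
    dropped: dict[str, str] = {}
    survivors = []
    for a in assocs:
        if a.pval < p_threshold:
            survivors.append(a)
        else:
            dropped[a.snp_id] = f"p={a.pval:.3g} >= {p_threshold:.3g}"
    if not survivors:
        raise ValueError(f"no instruments: no SNP met p < {p_threshold:.3g}")

    survivors.sort(key=lambda a: (a.pval, a.snp_id))
    kept: list[SnpAssociation] = []
    if ld_r2 is None:
        logger.info("select_instruments: no LD matrix supplied; p-filter only")
        kept = survivors
    else:
        pool = list(survivors)
        while pool:
            best = pool.pop(0)
            kept.append(best)
            still = []
            for a in pool:
                r2 = _r2_lookup(ld_r2, best.snp_id, a.snp_id)
                if r2 >= r2_max:
                    dropped[a.snp_id] = f"clumped: r2={r2:.3g} with {best.snp_id}"
                else:
                    still.append(a)
            pool = still
    logger.info(
        "select_instruments: kept %d of %d (p<%.3g, clump r2<%g)",
        len(kept), len(assocs), p_threshold, r2_max,
    )
    return Selection(snps=kept, p_threshold=p_threshold, r2_max=r2_max,
                     ld_supplied=ld_r2 is not None, dropped=dropped)


def _oriented_outcome(exp: SnpAssociation, out: SnpAssociation, eaf_window: float,
                      palindrome_policy: str):
    """Work out orientation of an outcome record relative to the exposure record.

    Returns (outcome_beta, action, note) or (None, drop_action, note).
    """
    ea, oa = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if exp.is_palindromic:
        # letters alone cannot distinguish strand; alleles must at least match as a set
        if {ea_o, oa_o} != {ea, oa}:
            return None, "dropped_incompatible", f"alleles {ea_o}/{oa_o} vs {ea}/{oa}"
        if palindrome_policy == "drop":
            return None, "dropped_palindromic", "palindromic (policy=drop)"
        ambiguous = (
            exp.eaf is None
            or out.eaf is None
            or abs(exp.eaf - 0.5) <= eaf_window
            or abs(out.eaf - 0.5) <= eaf_window
        )
        if ambiguous:
            return None, "dropped_palindromic", "palindromic with ambiguous frequency"
        nominal_flip = (ea_o, oa_o) == (oa, ea)
        eaf_eff = 1.0 - out.eaf if nominal_flip else out.eaf
        if (exp.eaf - 0.5) * (eaf_eff - 0.5) < 0:
            # frequencies disagree: the outcome record is on the other strand,
            # which for a palindrome toggles the nominal orientation
            nominal_flip = not nominal_flip
            note = "palindromic, aligned by frequency (strand-corrected)"
        else:
            note = "palindromic, aligned by frequency"
        if nominal_flip:
            return -out.beta, "flipped", note
        return out.beta, "kept", note

    if (ea_o, oa_o) == (ea, oa):
        return out.beta, "kept", None
    if (ea_o, oa_o) == (oa, ea):
        return -out.beta, "flipped", None
    cea, coa = COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)
    if (cea, coa) == (ea, oa):
        return out.beta, "kept", "strand flip"
    if (cea, coa) == (oa, ea):
        return -out.beta, "flipped", "strand flip"
    return None, "dropped_incompatible", f"alleles {ea_o}/{oa_o} vs {ea}/{oa}"


def harmonise(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindrome_policy: str = "infer",
    eaf_window: float = 0.08,
) -> list[HarmonisedInstrument]:
    """Align outcome effect alleles with exposure effect alleles.

    ``palindrome_policy``:

    * ``"infer"`` (default) — strand-ambiguous (A/T, C/G) pairs are oriented
      by effect-allele-frequency agreement, unless either frequency is
      missing or within ``eaf_window`` of 0.5, in which case the pair is
      dropped (``dropped_palindromic``);
    * ``"drop"`` — all palindromic pairs dropped.

    Every exposure SNP appears in the result exactly once with an explicit
    action; SNPs absent from the outcome become ``dropped_missing``.
    """
    if palindrome_policy not in ("infer", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    by_id = {o.snp_id: o for o in outcome}
    out: list[HarmonisedInstrument] = []
    for e in exposure:
        o = by_id.get(e.snp_id)
        if o is None:
            out.append(HarmonisedInstrument(e.snp_id, e.beta, e.se, None, None,
                                            "dropped_missing", note="absent from outcome"))
            continue
        beta, action, note = _oriented_outcome(e, o, eaf_window, palindrome_policy)
        if beta is None:
            out.append(HarmonisedInstrument(e.snp_id, e.beta, e.se, None, None, action, note=note))
        else:
            out.append(HarmonisedInstrument(e.snp_id, e.beta, e.se, beta, o.se, action, note=note))
    counts: dict[str, int] = {}
    for h in out:
        counts[h.action] = counts.get(h.action, 0) + 1
    logger.info("harmonise: %s", counts)
    return out


#: required columns of a proxy table
PROXY_COLUMNS = ("target", "proxy", "r2", "proxy_effect_allele", "proxy_other_allele")


def substitute_proxies(
    missing: Sequence[HarmonisedInstrument],
    proxy_table: pd.DataFrame,
    outcome: Sequence[SnpAssociation],
    r2_min: float = 0.8,
) -> list[HarmonisedInstrument]:
    """Replace ``dropped_missing`` instruments with their best LD proxy.

    ``proxy_table`` rows carry (target, proxy, r2, proxy_effect_allele,
    proxy_other_allele), where ``proxy_effect_allele`` is the proxy allele
    corresponding to the target's exposure effect allele.  The best proxy
    with r2 strictly above ``r2_min`` that is present in the outcome is
    substituted; otherwise the record stays dropped with a diagnostic.
    """
    for c in PROXY_COLUMNS:
        if c not in proxy_table.columns:
            raise ValueError(f"proxy table missing column {c!r}")
    by_id = {o.snp_id: o for o in outcome}
    out: list[HarmonisedInstrument] = []
    for h in missing:
        if h.action != "dropped_missing":
            out.append(h)
            continue
        rows = proxy_table[proxy_table["target"] == h.snp_id]
        rows = rows[rows["r2"] > r2_min]
        rows = rows[rows["proxy"].isin(by_id)]
        if rows.empty:
            out.append(replace(h, note=f"no proxy with r2 > {r2_min} in outcome"))
            continue
        # argmax on r2, ties broken lexicographically for determinism
        rows = rows.sort_values(["r2", "proxy"], ascending=[False, True])
        row = rows.iloc[0]
        o = by_id[row["proxy"]]
        pea, poa = str(row["proxy_effect_allele"]).upper(), str(row["proxy_other_allele"]).upper()
        if (o.effect_allele, o.other_allele) == (pea, poa):
            beta = o.beta
        elif (o.effect_allele, o.other_allele) == (poa, pea):
            beta = -o.beta
        elif (COMPLEMENT.get(o.effect_allele), COMPLEMENT.get(o.other_allele)) == (pea, poa):
            beta = o.beta
        elif (COMPLEMENT.get(o.effect_allele), COMPLEMENT.get(o.other_allele)) == (poa, pea):
            beta = -o.beta
        else:
            out.append(replace(h, note=f"proxy {o.snp_id} alleles irreconcilable"))
            continue
        out.append(
            HarmonisedInstrument(
                h.snp_id, h.exposure_beta, h.exposure_se, beta, o.se,
                "proxy_substituted", proxy_id=o.snp_id, proxy_r2=float(row["r2"]),
            )
        )
    return out


def f_statistics(instruments) -> tuple[list[float], float]:
    """Per-SNP F = (beta/se)^2 on the exposure side, and the arithmetic mean.

    Emits :class:`WeakInstrumentWarning` when any F falls below 10.  Accepts
    an :class:`InstrumentSet` or a sequence of usable instruments; when given
    an InstrumentSet its ``per_snp_f``/``mean_f`` fields are filled in.
    """
    target = instruments if isinstance(instruments, InstrumentSet) else None
    seq = instruments.instruments if target is not None else instruments
    fs = [(h.exposure_beta / h.exposure_se) ** 2 for h in seq if h.usable]
    if not fs:
        raise ValueError("no usable instruments for F statistics")
    mean_f = float(np.mean(fs))
    if min(fs) < WEAK_F_THRESHOLD:
        warnings.warn(
            f"weak instrument present: min F = {min(fs):.2f} < {WEAK_F_THRESHOLD:g}",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    if target is not None:
        target.per_snp_f = fs
        target.mean_f = mean_f
    return fs, mean_f


def build_instrument_set(
    biomarker_name: str,
    harmonised: Sequence[HarmonisedInstrument],
    p_threshold: float = 5e-8,
    r2_clump_threshold: float = 0.01,
) -> InstrumentSet:
    """Assemble the usable subset of harmonised records into an InstrumentSet."""
    usable = [h for h in harmonised if h.usable]
    if not usable:
        raise ValueError(f"{biomarker_name}: no usable instruments after harmonisation")
    s = InstrumentSet(biomarker_name, usable, p_threshold, r2_clump_threshold)
    f_statistics(s)
    return s
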