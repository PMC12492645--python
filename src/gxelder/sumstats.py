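"""Reading, validation, and harmonization of association summary statistics.

Supported dialects:

* ``generic-tsv`` / ``ldsc-sumstats`` — tab-separated with columns
  ``SNP, A1, A2, Z, N`` (A1 is the effect allele).  If ``Z`` is absent it is
  derived as ``BETA/SE`` when both are present.
* ``plink2-glm-linear`` — a ``.glm.linear``-style table whose ``TEST`` column
  distinguishes additive (``ADD``) from interaction rows; the caller selects
  which row type to keep.

Harmonization intersects the GWAS and interaction-scan (GWIS) variant sets
with the LD reference, orders variants as the reference does, flips Z-score
signs where a scan's effect allele is the reference's other allele, and
removes strand-ambiguous (A/T, C/G) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "HarmonizedPair",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = set(_COMPLEMENT)

DIALECTS = ("generic-tsv", "ldsc-sumstats", "plink2-glm-linear")


@dataclass
class SummaryStats:
    """Validated per-variant Z-score table for one association scan."""

    table: pd.DataFrame  # columns: variant_id, effect_allele, other_allele, z, n
    #: optional per-variant metadata columns carried through: chrom, pos

    def __post_init__(self) -> None:
        t = self.table
        required = ["variant_id", "effect_allele", "other_allele", "z", "n"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"summary statistics missing column(s): {missing}")
        if len(t) == 0:
            raise ValueError("summary statistics table is empty")
        if t["variant_id"].duplicated().any():
            dup = t.loc[t["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        if not np.isfinite(t["z"].to_numpy(float)).all():
            raise ValueError("non-finite Z-score present")
        if (t["n"].to_numpy(float) <= 0).any():
            raise ValueError("sample size must be positive")
        bad = ~(
            t["effect_allele"].isin(_VALID_ALLELES)
            & t["other_allele"].isin(_VALID_ALLELES)
        )
        if bad.any():
            raise ValueError(
                f"invalid allele code at variant {t.loc[bad, 'variant_id'].iloc[0]}"
            )
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect and other allele identical for some variant")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_scalar(self) -> float:
        """Scan-wide sample size: median of per-variant n."""
        return float(self.table["n"].median())


def _finish(df: pd.DataFrame, path: str | Path) -> SummaryStats:
    n_in = len(df)
    df = df.dropna(subset=["z", "n"])
    df = df[np.isfinite(df["z"].astype(float))]
    dropped = n_in - len(df)
    if dropped:
        logger.info("%d row(s) removed with missing z or n from %s", dropped, path)
    if len(df) == 0:
        raise ValueError(f"no usable rows in {path}")
    df = df.astype({"z": float, "n": float})
    return SummaryStats(df.reset_index(drop=True))


def read_sumstats(
    path: str | Path,
    dialect: str = "generic-tsv",
    interaction: bool = False,
    interaction_test: str | None = None,
) -> SummaryStats:
    """Read one association scan.

    For the ``plink2-glm-linear`` dialect, ``interaction=True`` keeps the
    SNPxE interaction rows (``TEST`` containing ``x``, or exactly
    ``interaction_test`` when given); otherwise the ``ADD`` rows are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect in ("generic-tsv", "ldsc-sumstats"):
        raw = pd.read_csv(path, sep="\t", na_values=["NA", ".", ""])
        for col in ("SNP", "A1", "A2", "N"):
            if col not in raw.columns:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        if "Z" not in raw.columns:
            if {"BETA", "SE"}.issubset(raw.columns):
                raw["Z"] = raw["BETA"] / raw["SE"]
            else:
                raise ValueError(f"missing mandatory column 'Z' in {path}")
        df = pd.DataFrame(
            {
                "variant_id": raw["SNP"].astype(str),
                "effect_allele": raw["A1"].astype(str).str.upper(),
                "other_allele": raw["A2"].astype(str).str.upper(),
                "z": raw["Z"],
                "n": raw["N"],
            }
        )
        return _finish(df, path)

    # plink2 .glm.linear-style
    raw = pd.read_csv(path, sep=r"\s+", na_values=["NA", "."])
    raw.columns = [c.lstrip("#") for c in raw.columns]
    needed = ["ID", "A1", "TEST", "OBS_CT"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column {missing[0]!r} in {path}")
    if interaction:
        if interaction_test is not None:
            keep = raw["TEST"] == interaction_test
        else:
            keep = raw["TEST"].str.contains("x", case=False, regex=False)
    else:
        keep = raw["TEST"] == "ADD"
    raw = raw[keep]
    if "Z_STAT" in raw.columns:
        z = raw["Z_STAT"]
    elif "T_STAT" in raw.columns:
        z = raw["T_STAT"]
    elif {"BETA", "SE"}.issubset(raw.columns):
        z = raw["BETA"] / raw["SE"]
    else:
        raise ValueError(f"missing mandatory column 'Z_STAT' in {path}")
    # other allele: REF unless ALT equals A1 is violated; PLINK2 A1 is the
    # counted (effect) allele, the other allele is REF when A1 == ALT.
    if {"REF", "ALT"}.issubset(raw.columns):
        other = np.where(raw["A1"] == raw["ALT"], raw["REF"], raw["ALT"])
    else:
        raise ValueError(f"missing mandatory column 'REF'/'ALT' in {path}")
    df = pd.DataFrame(
        {
            "variant_id": raw["ID"].astype(str),
            "effect_allele": raw["A1"].astype(str).str.upper(),
            "other_allele": pd.Series(other, index=raw.index).astype(str).str.upper(),
            "z": z,
            "n": raw["OBS_CT"],
        }
    )
    if "CHROM" in raw.columns:
        df["chrom"] = raw["CHROM"].astype(str)
    if "POS" in raw.columns:
        df["pos"] = raw["POS"].astype(int)
    return _finish(df, path)


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write a scan back to the generic TSV dialect (SNP, A1, A2, Z, N)."""
    out = pd.DataFrame(
        {
            "SNP": ss.table["variant_id"],
            "A1": ss.table["effect_allele"],
            "A2": ss.table["other_allele"],
            "Z": ss.table["z"],
            "N": ss.table["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


@dataclass
class HarmonizedPair:
    """Scans aligned to the LD reference variant order.

    ``z_g``/``z_i`` (and optionally ``z_e``) are sign-consistent with the
    reference effect alleles.  ``n_overlap`` is the known sample overlap of
    the two scans, or None; it only enters intercept terms, never the
    parameter estimates, so it may remain unknown.
    """

    variant_ids: list[str]
    z_g: np.ndarray
    z_i: np.ndarray
    n_g: float
    n_i: float
    z_e: np.ndarray | None = None
    n_e: float | None = None
    n_overlap: float | None = None
    n_dropped: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.variant_ids)


def _align_one(
    ss: SummaryStats, ref: pd.DataFrame, label: str
) -> tuple[pd.Series, pd.Series]:
    """Return (z aligned to ref orientation indexed by variant_id, kept ids)."""
    t = ss.table.set_index("variant_id")
    common = ref.index.intersection(t.index)
    t = t.loc[common]
    r = ref.loc[common]
    same = (t["effect_allele"] == r["effect_allele"]) & (
        t["other_allele"] == r["other_allele"]
    )
    flipped = (t["effect_allele"] == r["other_allele"]) & (
        t["other_allele"] == r["effect_allele"]
    )
    mismatched = ~(same | flipped)
    if mismatched.any():
        logger.info(
            "%s scan: %d variant(s) dropped with allele pair matching neither "
            "reference orientation",
            label,
            int(mismatched.sum()),
        )
    z = t["z"].where(same, -t["z"])[~mismatched]
    return z, int(mismatched.sum())


def harmonize(
    g: SummaryStats,
    i: SummaryStats,
    reference_variants: pd.DataFrame,
    e: SummaryStats | None = None,
    n_overlap: float | None = None,
) -> HarmonizedPair:
    """Align scans to each other and to the LD reference.

    ``reference_variants`` needs columns ``variant_id``, ``effect_allele``,
    ``other_allele`` in reference (genome) order.  Strand-ambiguous variants
    are removed; variants whose allele pair matches neither orientation are
    dropped and counted.
    """
    ref = reference_variants.copy()
    for col in ("variant_id", "effect_allele", "other_allele"):
        if col not in ref.columns:
            raise ValueError(f"reference_variants missing column {col!r}")
    ref["effect_allele"] = ref["effect_allele"].str.upper()
    ref["other_allele"] = ref["other_allele"].str.upper()
    ambiguous = _is_ambiguous(ref["effect_allele"], ref["other_allele"])
    n_ambig = int(ambiguous.sum())
    if n_ambig:
        logger.info("%d strand-ambiguous variant(s) removed", n_ambig)
    ref = ref[~ambiguous].set_index("variant_id")

    dropped: dict[str, int] = {"ambiguous": n_ambig}
    scans = {"gwas": g, "gwis": i}
    if e is not None:
        scans["gwas_e"] = e
    aligned: dict[str, pd.Series] = {}
    for label, ss in scans.items():
        z, n_bad = _align_one(ss, ref, label)
        aligned[label] = z
        dropped[f"{label}_allele_mismatch"] = n_bad

    keep = ref.index
    for z in aligned.values():
        keep = keep.intersection(z.index)
    # reference order
    keep = [v for v in ref.index if v in set(keep)]
    if len(keep) == 0:
        raise ValueError("no variants shared by the scans and the LD reference")

    return HarmonizedPair(
        variant_ids=list(keep),
        z_g=aligned["gwas"].loc[keep].to_numpy(float),
        z_i=aligned["gwis"].loc[keep].to_numpy(float),
        n_g=g.n_scalar,
        n_i=i.n_scalar,
        z_e=aligned["gwas_e"].loc[keep].to_numpy(float) if e is not None else None,
        n_e=e.n_scalar if e is not None else None,
        n_overlap=n_overlap,
        n_dropped=dropped,
    )
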