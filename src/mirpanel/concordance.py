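"""Cross-platform comparison of a panel DE table against an external DE table.

Names are matched in two stages: exact on normalized names (lowercase,
"hsa-" prefix stripped), then by stem (arm suffix -5p/-3p removed) among the
leftovers, with ambiguous stems left unmatched. Concordance is agreement in
the sign of the two log2 fold changes; zero is sign-indeterminate and never
concordant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_ARM_SUFFIX = re.compile(r"-(5p|3p)$")

PAIR_COLUMNS = (
    "panel_name",
    "external_name",
    "match_stage",
    "panel_log2fc",
    "panel_fdr",
    "external_log2fc",
    "external_fdr",
    "concordant",
    "panel_significant",
)


def normalize_name(name: str) -> str:
    name = str(name).strip().lower()
    if name.startswith("hsa-"):
        name = name[4:]
    return name


def stem_name(name: str) -> str:
    """Name with the arm suffix removed, after normalization."""
    return _ARM_SUFFIX.sub("", normalize_name(name))


def match_mirna_names(
    panel_names: list[str] | tuple[str, ...],
    external_names: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """Two-stage one-to-one name matching.

    Stage 1 pairs exact normalized names; stage 2 pairs remaining names whose
    stems match uniquely on both sides. Stems shared by several unmatched
    names on either side are ambiguous and stay unmatched. Returns a frame
    with columns panel_name, external_name, match_stage.
    """
    panel_names = list(dict.fromkeys(str(n) for n in panel_names))
    external_names = list(dict.fromkeys(str(n) for n in external_names))

    ext_by_norm: dict[str, str] = {}
    for name in external_names:
        ext_by_norm.setdefault(normalize_name(name), name)

    pairs = []
    matched_ext = set()
    unmatched_panel = []
    for name in panel_names:
        ext = ext_by_norm.get(normalize_name(name))
        if ext is not None and ext not in matched_ext:
            pairs.append((name, ext, "exact"))
            matched_ext.add(ext)
        else:
            unmatched_panel.append(name)

    rem_ext = [n for n in external_names if n not in matched_ext]
    panel_stems: dict[str, list[str]] = {}
    for name in unmatched_panel:
        panel_stems.setdefault(stem_name(name), []).append(name)
    ext_stems: dict[str, list[str]] = {}
    for name in rem_ext:
        ext_stems.setdefault(stem_name(name), []).append(name)
    for stem, p_names in panel_stems.items():
        e_names = ext_stems.get(stem, [])
        if len(p_names) == 1 and len(e_names) == 1:
            pairs.append((p_names[0], e_names[0], "stem"))

    return pd.DataFrame(pairs, columns=["panel_name", "external_name", "match_stage"])


def read_external_de(path) -> pd.DataFrame:
    """Read an external DE table (mirna, log2fc, fdr), one row per name.

    Duplicate names after normalization keep the record with the smallest FDR.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mirna", "log2fc", "fdr") if c not in df.columns]
    if missing:
        raise ValueError(f"external DE table missing columns: {missing}")
    df = df.copy()
    df["_norm"] = df["mirna"].map(normalize_name)
    df = df.sort_values("fdr", kind="stable").drop_duplicates("_norm")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
        raise ValueError("external DE table contains non-finite log2fc")
    return df.drop(columns="_norm").reset_index(drop=True)


@dataclass
class ConcordanceReport:
    """Matched pairs, sign agreement summary and the concordant+significant subset."""

    pairs: pd.DataFrame
    n_matched: int
    n_concordant: int
    percent_concordant: float  # NaN when nothing matched
    concordant_significant: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    n_matched=self.n_matched,
                    n_concordant=self.n_concordant,
                    percent_concordant=self.percent_concordant,
                    n_concordant_significant=len(self.concordant_significant),
                )
            ]
        )


def _signs_agree(x: float, y: float) -> bool:
    return bool(np.sign(x) == np.sign(y) and x != 0 and y != 0)


def concordance_report(
    panel_de: pd.DataFrame,
    external_de: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> ConcordanceReport:
    """Match names, flag per-pair sign concordance, and summarize.

    The concordant-and-significant subset applies the dual panel-side filter
    |log2 fold regulation| > lfc_threshold and FDR < fdr_threshold; external
    significance is reported but not required. Zero matches yields an empty
    report with an undefined (NaN) percentage rather than an error.
    """
    if panel_de.empty or external_de.empty:
        raise ValueError("both DE tables must be non-empty")
    matches = match_mirna_names(
        panel_de["mirna"].tolist(), external_de["mirna"].tolist()
    )
    panel_idx = panel_de.set_index("mirna")
    ext_idx = external_de.set_index("mirna")

    rows = []
    for _, m in matches.iterrows():
        prec = panel_idx.loc[m["panel_name"]]
        erec = ext_idx.loc[m["external_name"]]
        p_lfc = float(prec["log2_fold_reg"])
        e_lfc = float(erec["log2fc"])
        p_fdr = float(prec["fdr"]) if np.isfinite(prec.get("fdr", np.nan)) else np.nan
        rows.append(
            dict(
                panel_name=m["panel_name"],
                external_name=m["external_name"],
                match_stage=m["match_stage"],
                panel_log2fc=p_lfc,
                panel_fdr=p_fdr,
                external_log2fc=e_lfc,
                external_fdr=float(erec["fdr"]),
                concordant=_signs_agree(p_lfc, e_lfc),
                panel_significant=bool(
                    np.isfinite(p_fdr)
                    and p_fdr < fdr_threshold
                    and abs(p_lfc) > lfc_threshold
                ),
            )
        )
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    n_matched = len(pairs)
    n_concordant = int(pairs["concordant"].sum()) if n_matched else 0
    percent = 100.0 * n_concordant / n_matched if n_matched else float("nan")
    subset = (
        pairs[pairs["concordant"] & pairs["panel_significant"]].reset_index(drop=True)
        if n_matched
        else pairs
    )
    return ConcordanceReport(
        pairs=pairs,
        n_matched=n_matched,
        n_concordant=n_concordant,
        percent_concordant=percent,
        concordant_significant=subset,
    )
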