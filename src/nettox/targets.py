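"""Target-list standardization, context-aware filtering, and intersections.

Implements the Venn stage of the triage pipeline: curated disease and
chemical target lists are standardized to uppercase symbols with aliases
resolved, optionally filtered by annotation context (direct-interaction
CTD entries, top fit-score fraction of pharmacophore hits, detectable
expression), and intersected with the DEG list to form the candidate set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TargetSet

DEFAULT_FIT_TOP_FRAC = 0.2


@dataclass
class CandidateSet:
    """Three-way intersection with provenance (parent names and sizes)."""

    symbols: set[str]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.symbols)


def _check_alias_map(alias_map: dict[str, str]) -> None:
    for k, v in alias_map.items():
        if v in alias_map and alias_map[v] != v:
            raise ValueError(f"alias map is not idempotent at {k!r} -> {v!r} -> {alias_map[v]!r}")


def standardize(
    entries: pd.DataFrame,
    alias_map: dict[str, str] | None = None,
    name: str = "targets",
    keep_species: tuple[str, ...] = ("HOMO SAPIENS",),
) -> TargetSet:
    """Map aliases, uppercase, merge duplicates, drop empty symbols.

    Duplicate symbols merge keeping the maximum fit score and the union of
    interaction-type and source labels (pipe-joined). Entries labelled with a
    species outside ``keep_species`` are dropped; unlabeled entries pass.
    Dropped-entry counts are recorded on the returned set.
    """
    alias_map = {str(k).strip().upper(): str(v).strip().upper() for k, v in (alias_map or {}).items()}
    _check_alias_map(alias_map)
    df = entries.copy()
    if "symbol" not in df.columns:
        raise ValueError("entries must have a 'symbol' column")
    df["symbol"] = df["symbol"].astype(str).str.strip().str.upper()
    df["symbol"] = df["symbol"].map(lambda s: alias_map.get(s, s))
    n_before = len(df)
    df = df[(df["symbol"] != "") & (df["symbol"] != "NAN")]
    if "species" in df.columns:
        sp = df["species"].astype(str).str.strip().str.upper()
        df = df[sp.isin(keep_species) | df["species"].isna() | (sp == "NAN") | (sp == "")]
    n_dropped = n_before - len(df)

    def _merge(group: pd.DataFrame) -> pd.Series:
        out = {"symbol": group.name}
        for col in ("source", "interaction_type"):
            if col in group.columns:
                labels = sorted(
                    {x for cell in group[col].dropna() for x in str(cell).split("|") if x}
                )
                out[col] = "|".join(labels) if labels else np.nan
            else:
                out[col] = np.nan
        out["fit_score"] = group["fit_score"].max() if "fit_score" in group.columns else np.nan
        if "species" in group.columns and group["species"].notna().any():
            out["species"] = group["species"].dropna().iloc[0]
        else:
            out["species"] = np.nan
        return pd.Series(out)

    if len(df) == 0:
        ts = TargetSet(name, pd.DataFrame(columns=["symbol"]))
    else:
        merged = df.groupby("symbol", sort=True).apply(_merge, include_groups=False)
        ts = TargetSet(name, merged.reset_index(drop=True))
    ts.n_dropped = n_dropped
    return ts


def context_filter(
    chem: TargetSet,
    matrices: ExpressionMatrix | list[ExpressionMatrix],
    direct_only: bool = True,
    fit_top_frac: float = DEFAULT_FIT_TOP_FRAC,
) -> TargetSet:
    """Context-aware filtering of a chemical target set.

    Per source: CTD-derived entries must be annotated as direct interactions
    (when ``direct_only``); pharmacophore-mapping entries must reach the top
    ``fit_top_frac`` of that source's fit scores (inclusive at the cutoff
    quantile, linear interpolation). All survivors must additionally have
    detectable expression (> 0 in at least one sample of any provided
    matrix); symbols absent from every matrix are removed.
    """
    if not 0 < fit_top_frac <= 1:
        raise ValueError("fit_top_frac must be in (0, 1]")
    if isinstance(matrices, ExpressionMatrix):
        matrices = [matrices]
    df = chem.entries.copy()
    src = df["source"].fillna("").astype(str).str.lower()
    is_ctd = src.str.contains("ctd")
    is_pm = src.str.contains("pharmmapper")

    keep = pd.Series(True, index=df.index)
    if direct_only:
        def _is_direct(cell: str) -> bool:
            tokens = [t.strip().lower() for t in str(cell).split("|")]
            return any(t == "direct" or (("direct" in t) and ("indirect" not in t)) for t in tokens)

        direct = df["interaction_type"].fillna("").map(_is_direct)
        keep &= ~is_ctd | direct
    if fit_top_frac < 1:
        pm_scores = df.loc[is_pm, "fit_score"].astype(float)
        if is_pm.any():
            if pm_scores.isna().all():
                raise ValueError("pharmmapper entries lack fit scores; cannot apply fit_top_frac")
            cutoff = np.nanquantile(pm_scores.to_numpy(float), 1.0 - fit_top_frac)
            keep &= ~is_pm | (df["fit_score"].astype(float) >= cutoff)

    detectable: set[str] = set()
    for m in matrices:
        mask = (m.values > 0).any(axis=1)
        detectable |= set(m.values.index[mask])
    keep &= df["symbol"].isin(detectable)

    out = TargetSet(chem.name + "_filtered", df[keep])
    return out


def intersect3(deg_symbols: set[str], disease: TargetSet, chem: TargetSet) -> CandidateSet:
    """Exact three-way intersection: DEGs x disease targets x chemical targets."""
    provenance = {
        "deg": len(deg_symbols),
        disease.name: len(disease),
        chem.name: len(chem),
    }
    if not deg_symbols or len(disease) == 0 or len(chem) == 0:
        warnings.warn("empty parent set in three-way intersection")
        return CandidateSet(set(), provenance)
    return CandidateSet(set(deg_symbols) & disease.symbols & chem.symbols, provenance)


def drug_compare(cand_a: CandidateSet, cand_b: CandidateSet) -> tuple[set, set, set]:
    """Partition two drug-specific candidate sets into shared / A-only / B-only."""
    shared = cand_a.symbols & cand_b.symbols
    return shared, cand_a.symbols - shared, cand_b.symbols - shared


def venn_summary(deg_symbols: set[str], disease: TargetSet, chem: TargetSet) -> dict:
    """Parent sizes plus pairwise and three-way overlap counts (JSON-ready)."""
    d, c, g = disease.symbols, chem.symbols, set(deg_symbols)
    return {
        "sizes": {"deg": len(g), "disease": len(d), "chemical": len(c)},
        "pairwise": {
            "deg_disease": len(g & d),
            "deg_chemical": len(g & c),
            "disease_chemical": len(d & c),
        },
        "three_way": len(g & d & c),
    }


def write_venn_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
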