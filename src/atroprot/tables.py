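"""Domain containers and TSV readers/writers for quantification tables.

The dialect mirrors MaxQuant text exports: tab-separated, UTF-8, "." decimal,
empty cell or "NaN" meaning missing.  Per-sample columns are named in the
MaxQuant style, e.g. ``Ratio H/L <sample>`` and ``Intensity L <sample>``.

Site coordinates are 1-based on the protein sequence (PTM-site convention).
``protein_id`` is the only key; duplicate gene names are allowed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "denervated")
ASSAYS = ("expression", "pulse", "sites")

#: MaxQuant applies a minimal number of peptide ratio measurements before a
#: protein H/L ratio is reported; ratios with fewer counts are dropped.
MIN_RATIO_COUNT = 2


class TableFormatError(ValueError):
    """A required column is missing or a structural invariant is violated."""


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Maps every measured sample column to (condition, time, replicate, assay).

    ``time_day`` is days post-denervation.  The study design uses days
    1/4/7/14 for expression and 4/7/11 for the label pulse, but arbitrary
    positive time points are accepted.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "time_day", "replicate", "assay")

    def __post_init__(self) -> None:
        f = self.frame
        for col in self.REQUIRED:
            if col not in f.columns:
                raise TableFormatError(f"design table lacks column {col!r}")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableFormatError(f"duplicate sample_id {dup!r} in design")
        bad_cond = set(f["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise TableFormatError(f"unknown condition(s) {sorted(bad_cond)}")
        bad_assay = set(f["assay"]) - set(ASSAYS)
        if bad_assay:
            raise TableFormatError(f"unknown assay(s) {sorted(bad_assay)}")
        if (f["time_day"] < 0).any():
            raise TableFormatError("time_day must be non-negative")
        if (f["replicate"] < 1).any():
            raise TableFormatError("replicate must be a positive integer")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, *, condition: str | None = None, time_day: float | None = None,
               assay: str | None = None) -> "SampleDesign":
        f = self.frame
        if condition is not None:
            f = f[f["condition"] == condition]
        if time_day is not None:
            f = f[f["time_day"] == time_day]
        if assay is not None:
            f = f[f["assay"] == assay]
        return SampleDesign(f.copy())

    def times(self, assay: str) -> list[float]:
        t = sorted(self.frame.loc[self.frame["assay"] == assay, "time_day"].unique())
        return t

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein quantification
# ---------------------------------------------------------------------------

@dataclass
class ProteinQuantTable:
    """Per-protein light/heavy intensities, H/L ratios and ratio counts.

    All per-sample frames are indexed by ``protein_id`` with one column per
    sample of the associated design.  ``hl_ratio`` is heavy/light against the
    common spike-in standard; it is missing wherever fewer than
    ``MIN_RATIO_COUNT`` peptide ratios supported it.
    """

    proteins: pd.DataFrame          # index protein_id; column gene_name
    light: pd.DataFrame
    heavy: pd.DataFrame
    hl_ratio: pd.DataFrame
    ratio_count: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        idx = self.proteins.index
        if idx.duplicated().any():
            raise TableFormatError(
                f"duplicate protein_id {idx[idx.duplicated()][0]!r}")
        for name in ("light", "heavy", "hl_ratio", "ratio_count"):
            fr = getattr(self, name)
            if not fr.index.equals(idx):
                raise TableFormatError(f"{name} index does not match proteins")

    @property
    def protein_ids(self) -> pd.Index:
        return self.proteins.index

    def apply_min_ratio_count(self, min_count: int = MIN_RATIO_COUNT) -> "ProteinQuantTable":
        """Mask H/L ratios with insufficient peptide evidence (idempotent)."""
        masked = self.hl_ratio.where(self.ratio_count >= min_count)
        return ProteinQuantTable(self.proteins, self.light, self.heavy,
                                 masked, self.ratio_count, self.design)

    def log2_lh(self) -> pd.DataFrame:
        """log2(light/heavy) per sample; the spike-in standard is the heavy side."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return -np.log2(self.hl_ratio)


def read_protein_table(path: str | Path, design: SampleDesign,
                       min_ratio_count: int = MIN_RATIO_COUNT) -> ProteinQuantTable:
    """Read a proteinGroups-like TSV resolved against *design*.

    Unparseable numeric cells become missing (counted and logged); the
    minimal-ratio-count mask is applied on read.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Protein IDs", "Gene names"):
        if col not in raw.columns:
            raise TableFormatError(f"protein table lacks column {col!r}")
    sids = design.sample_ids
    blocks = {"light": "Intensity L", "heavy": "Intensity H",
              "hl_ratio": "Ratio H/L", "ratio_count": "Ratio H/L count"}
    for prefix in blocks.values():
        for sid in sids:
            if f"{prefix} {sid}" not in raw.columns:
                raise TableFormatError(f"protein table lacks column {prefix} {sid!r}")

    pid = raw["Protein IDs"]
    if pid.duplicated().any():
        raise TableFormatError(
            f"duplicate protein_id {pid[pid.duplicated()].iloc[0]!r}")
    proteins = pd.DataFrame({"gene_name": raw["Gene names"].values},
                            index=pd.Index(pid, name="protein_id"))

    n_bad = 0
    frames = {}
    for attr, prefix in blocks.items():
        cols = {}
        for sid in sids:
            s = raw[f"{prefix} {sid}"].replace("", np.nan)
            num = pd.to_numeric(s, errors="coerce")
            n_bad += int((num.isna() & s.notna() & (s.str.lower() != "nan")).sum())
            cols[sid] = num
        frames[attr] = pd.DataFrame(cols).set_index(proteins.index)
    if n_bad:
        logger.warning("read_protein_table: %d unparseable numeric cells set to missing", n_bad)

    frames["ratio_count"] = frames["ratio_count"].fillna(0).astype(int)
    table = ProteinQuantTable(proteins, frames["light"], frames["heavy"],
                              frames["hl_ratio"], frames["ratio_count"], design)
    return table.apply_min_ratio_count(min_ratio_count)


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    out = pd.DataFrame({"Protein IDs": table.proteins.index,
                        "Gene names": table.proteins["gene_name"].values})
    for prefix, fr in (("Intensity L", table.light), ("Intensity H", table.heavy),
                       ("Ratio H/L", table.hl_ratio), ("Ratio H/L count", table.ratio_count)):
        for sid in table.design.sample_ids:
            out[f"{prefix} {sid}"] = fr[sid].values
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Diglycine sites
# ---------------------------------------------------------------------------

@dataclass
class SiteQuantTable:
    """Diglycine-remnant (K-epsilon-GG) site records with per-sample log2 ratios.

    ``sites`` carries site_id (index), protein_id, residue_position (1-based)
    and localization_ok; ``log2_ratio`` is den/ctrl per site per sample.
    """

    sites: pd.DataFrame
    log2_ratio: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if (self.sites["residue_position"] < 1).any():
            raise TableFormatError("residue_position must be >= 1")

    def valid(self) -> "SiteQuantTable":
        """Restrict to localized sites (and, if checked, lysine residues)."""
        keep = self.sites["localization_ok"].astype(bool)
        return SiteQuantTable(self.sites[keep].copy(), self.log2_ratio[keep].copy(),
                              self.design)


def read_site_table(path: str | Path, design: SampleDesign,
                    sequences: Mapping[str, str] | str | Path | None = None,
                    loc_prob_min: float = 0.75) -> SiteQuantTable:
    """Read a GlyGly-sites-like TSV; optionally validate positions on *sequences*.

    When sequences are supplied (a FASTA path or an id->sequence mapping),
    sites whose residue is not lysine, or whose position exceeds the protein
    length, are flagged ``localization_ok=False`` and excluded by
    :meth:`SiteQuantTable.valid`.
    """
    raw = pd.read_csv(path, sep="\t")
    for col in ("Site ID", "Protein", "Position", "Localization prob"):
        if col not in raw.columns:
            raise TableFormatError(f"site table lacks column {col!r}")
    if (raw["Position"] <= 0).any():
        raise TableFormatError("site Position must be positive (1-based)")

    sids = design.sample_ids
    ratio_cols = {}
    for sid in sids:
        col = f"Log2 ratio {sid}"
        if col not in raw.columns:
            raise TableFormatError(f"site table lacks column {col!r}")
        ratio_cols[sid] = pd.to_numeric(raw[col], errors="coerce")

    ok = raw["Localization prob"].astype(float) >= loc_prob_min
    sites = pd.DataFrame({
        "protein_id": raw["Protein"].values,
        "residue_position": raw["Position"].astype(int).values,
        "localization_ok": ok.values,
    }, index=pd.Index(raw["Site ID"], name="site_id"))

    if sequences is not None:
        if not isinstance(sequences, Mapping):
            from Bio import SeqIO
            sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
        n_excl = 0
        for sid_, row in sites.iterrows():
            seq = sequences.get(row["protein_id"])
            if seq is None:
                continue
            pos = row["residue_position"]
            if pos > len(seq) or seq[pos - 1].upper() != "K":
                sites.loc[sid_, "localization_ok"] = False
                n_excl += 1
        if n_excl:
            logger.warning("read_site_table: %d sites excluded (non-lysine or "
                           "out-of-range position)", n_excl)

    log2_ratio = pd.DataFrame(ratio_cols).set_index(sites.index)
    return SiteQuantTable(sites, log2_ratio, design)


def write_site_table(table: SiteQuantTable, path: str | Path) -> None:
    out = pd.DataFrame({
        "Site ID": table.sites.index,
        "Protein": table.sites["protein_id"].values,
        "Position": table.sites["residue_position"].values,
        "Localization prob": np.where(table.sites["localization_ok"], 1.0, 0.0),
    })
    for sid in table.design.sample_ids:
        out[f"Log2 ratio {sid}"] = table.log2_ratio[sid].values
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Category terms and their member proteins (a protein may be in many)."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if not members:
                raise TableFormatError(f"annotation term {tid!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationSet":
        f = pd.read_csv(path, sep="\t")
        for col in ("term_id", "term_name", "protein_id"):
            if col not in f.columns:
                raise TableFormatError(f"annotation table lacks column {col!r}")
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for tid, grp in f.groupby("term_id", sort=True):
            terms[tid] = set(grp["protein_id"])
            names[tid] = grp["term_name"].iloc[0]
        return cls(terms, names)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for tid in sorted(self.terms):
            for pid in sorted(self.terms[tid]):
                rows.append((tid, self.names.get(tid, tid), pid))
        pd.DataFrame(rows, columns=["term_id", "term_name", "protein_id"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Time profiles
# ---------------------------------------------------------------------------

@dataclass
class TimeProfileMatrix:
    """Proteins x time points of log2(den/ctrl), with replicate evidence counts.

    Cells backed by fewer than two replicate values are flagged low-evidence;
    they are kept for profile display but excluded from hypothesis tests.
    """

    values: pd.DataFrame    # index protein_id, columns time_day ascending
    n_obs: pd.DataFrame
    qvalues: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise TableFormatError("time columns must be strictly increasing")
        finite = self.values.to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise TableFormatError("profile values must be finite or missing")

    @property
    def times(self) -> list[float]:
        return list(self.values.columns)

    def low_evidence(self) -> pd.DataFrame:
        return self.n_obs < 2


# ---------------------------------------------------------------------------
# Result output + run manifest
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest: Mapping | None = None) -> list[Path]:
    """Write result tables as TSVs with deterministic column order.

    Returns the written paths.  ``manifest`` (parameters, seed, versions) is
    serialized as ``manifest.json``; it deliberately contains no timestamp so
    that identical runs produce byte-identical output directories.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = out / f"{name}.tsv"
        df = tables[name]
        df.to_csv(p, sep="\t", index=df.index.name is not None)
        written.append(p)
    if manifest is not None:
        p = out / "manifest.json"
        p.write_text(json.dumps(build_manifest(manifest), indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written


def build_manifest(params: Mapping) -> dict:
    import sklearn

    from . import __version__
    return {
        "parameters": _jsonable(params),
        "versions": {
            "atroprot": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
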