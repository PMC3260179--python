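"""Reading, validating and writing genotype data in STRUCTURE text format.

The in-memory model is a :class:`GenotypeTable`: a panel of loci (each with
declared allele codes), a sample sheet (sample id, population, continental
group, training flag) and an ``(n, L, 2)`` integer array of allele calls.
INDEL alleles are coded ``1`` (short) and ``2`` (long), with rare additional
length variants coded ``3``; missing data is ``-9`` and is always
whole-genotype (both allele slots missing together).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing allele call (STRUCTURE convention)
MISSING: int = -9

#: highest allele code the panel supports (1, 2 and the occasional 3)
MAX_ALLELE: int = 3


class FormatError(ValueError):
    """Raised when a genotype file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a table invariant."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one biallelic (or occasionally triallelic) INDEL locus."""

    marker_id: str
    allele_codes: tuple[int, ...] = (1, 2)
    rs_id: str = ""
    chromosome: str = ""
    position_bp: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.allele_codes) < 2:
            raise ValidationError(
                f"{self.marker_id}: at least two allele codes required"
            )
        if any(a < 1 or a > MAX_ALLELE for a in self.allele_codes):
            raise ValidationError(
                f"{self.marker_id}: allele codes must lie in 1..{MAX_ALLELE}"
            )
        if self.position_bp is not None and self.position_bp < 1:
            raise ValidationError(f"{self.marker_id}: position_bp must be >= 1")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid genotype matrix with sample metadata.

    Attributes
    ----------
    panel:
        One :class:`LocusDef` per locus, in column order.
    samples:
        DataFrame with columns ``sample_id``, ``population``, ``group``,
        ``popflag`` (0/1), one row per individual.
    calls:
        ``(n, L, 2)`` int array of allele codes; ``MISSING`` marks a missing
        genotype (both slots).
    """

    panel: list[LocusDef]
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.validate()

    # -- basic dimensions -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    @property
    def marker_ids(self) -> list[str]:
        return [loc.marker_id for loc in self.panel]

    @property
    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of missing genotypes."""
        return self.calls[:, :, 0] == MISSING

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if self.calls.shape != (n, L, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        required = {"sample_id", "population", "group", "popflag"}
        if not required.issubset(self.samples.columns):
            raise ValidationError(
                f"sample sheet must have columns {sorted(required)}"
            )
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        miss0 = self.calls[:, :, 0] == MISSING
        miss1 = self.calls[:, :, 1] == MISSING
        if not np.array_equal(miss0, miss1):
            bad = np.argwhere(miss0 != miss1)[0]
            raise ValidationError(
                "half-missing genotype at individual "
                f"{self.samples['sample_id'].iloc[bad[0]]}, locus "
                f"{self.panel[bad[1]].marker_id}"
            )
        for j, loc in enumerate(self.panel):
            col = self.calls[:, j, :]
            obs = col[col != MISSING]
            bad = ~np.isin(obs, loc.allele_codes)
            if bad.any():
                code = int(obs[bad][0])
                who = np.argwhere(
                    (col != MISSING) & ~np.isin(col, loc.allele_codes)
                )[0][0]
                raise ValidationError(
                    f"undeclared allele code {code} at marker {loc.marker_id}, "
                    f"sample {self.samples['sample_id'].iloc[who]}"
                )
        seen = set()
        for loc in self.panel:
            if loc.marker_id in seen:
                raise ValidationError(f"duplicate marker id {loc.marker_id}")
            seen.add(loc.marker_id)

    # -- helpers ----------------------------------------------------------
    def allele_index(self) -> np.ndarray:
        """Calls as 0-based allele indices; missing mapped to ``-1``."""
        idx = self.calls.astype(np.int64) - 1
        idx[self.calls == MISSING] = -1
        return idx

    def subset(self, mask: np.ndarray | Sequence[bool]) -> "GenotypeTable":
        """Row subset of individuals (boolean mask or index array)."""
        mask = np.asarray(mask)
        samples = self.samples.loc[mask].reset_index(drop=True) \
            if mask.dtype == bool else self.samples.iloc[mask].reset_index(drop=True)
        return GenotypeTable(self.panel, samples, self.calls[mask])

    def restrict_groups(self, groups: Iterable[str]) -> "GenotypeTable":
        keep = set(groups)
        return self.subset(self.samples["group"].isin(keep).to_numpy())

    def with_groups(self, label_map: Mapping[str, str]) -> "GenotypeTable":
        """Return a copy with ``group`` set from a population -> group map."""
        samples = self.samples.copy()
        samples["group"] = samples["population"].map(
            lambda p: label_map.get(p, p)
        )
        return GenotypeTable(self.panel, samples, self.calls.copy())

    def equals(self, other: "GenotypeTable") -> bool:
        if self.marker_ids != other.marker_ids:
            return False
        cols = ["sample_id", "population", "group", "popflag"]
        if not self.samples[cols].reset_index(drop=True).equals(
            other.samples[cols].reset_index(drop=True)
        ):
            return False
        a = np.sort(self.calls, axis=2)
        b = np.sort(other.calls, axis=2)
        return bool(np.array_equal(a, b))


def concat_tables(a: GenotypeTable, b: GenotypeTable) -> GenotypeTable:
    """Stack two tables sharing the same panel (reference + test cohorts)."""
    if a.marker_ids != b.marker_ids:
        raise ValidationError("cannot concatenate tables with different panels")
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    return GenotypeTable(a.panel, samples, np.concatenate([a.calls, b.calls]))


@dataclass
class FrequencyTable:
    """Per-group, per-locus allele-frequency vectors with copy counts.

    ``freqs`` is ``(G, L, MAX_ALLELE)`` over allele codes ``1..MAX_ALLELE``
    (undeclared codes carry frequency 0); ``n_copies`` is the number of
    observed allele copies (``2 n_observed``) behind each estimate, 0 for
    purely generative (simulator truth) tables.
    """

    groups: list[str]
    panel: list[LocusDef]
    freqs: np.ndarray
    n_copies: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n_copies = np.asarray(self.n_copies, dtype=float)
        G, L = len(self.groups), len(self.panel)
        if self.freqs.shape != (G, L, MAX_ALLELE):
            raise ValidationError(
                f"freqs shape {self.freqs.shape} != ({G}, {L}, {MAX_ALLELE})"
            )
        if self.n_copies.shape != (G, L):
            raise ValidationError("n_copies shape mismatch")
        if ((self.freqs < -1e-12) | (self.freqs > 1 + 1e-12)).any():
            raise ValidationError("frequencies outside [0, 1]")
        sums = self.freqs.sum(axis=2)
        observed = (self.n_copies > 0) | (sums > 0.5)
        if np.abs(sums[observed] - 1.0).max(initial=0.0) > 1e-9:
            raise ValidationError("frequency vectors must sum to 1")

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None

    def freq(self, group: str, marker_id: str) -> np.ndarray:
        """Frequency vector over the locus's declared allele codes."""
        g = self.group_index(group)
        li = [loc.marker_id for loc in self.panel].index(marker_id)
        codes = np.array(self.panel[li].allele_codes) - 1
        return self.freqs[g, li, codes]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (marker, group, allele, frequency, n_copies)."""
        rows = []
        for g, grp in enumerate(self.groups):
            for li, loc in enumerate(self.panel):
                for code in loc.allele_codes:
                    rows.append(
                        {
                            "marker_id": loc.marker_id,
                            "group": grp,
                            "allele": code,
                            "frequency": self.freqs[g, li, code - 1],
                            "n_copies": self.n_copies[g, li],
                        }
                    )
        return pd.DataFrame(rows)


def write_frequency_tsv(freqs: FrequencyTable, path: str | Path) -> None:
    freqs.to_frame().to_csv(path, sep="\t", index=False)


def read_frequency_tsv(
    path: str | Path, panel: Sequence[LocusDef] | None = None
) -> FrequencyTable:
    """Load a long-format allele-frequency TSV (transcribed published tables).

    Expected columns: ``marker_id``, ``group``, ``allele``, ``frequency`` and
    optionally ``n_copies``.  Markers absent from ``panel`` (if given) raise.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"marker_id", "group", "allele", "frequency"}
    if not needed.issubset(df.columns):
        raise FormatError(f"frequency TSV needs columns {sorted(needed)}")
    marker_order = list(dict.fromkeys(df["marker_id"]))
    if panel is None:
        panel = [
            LocusDef(
                m,
                tuple(sorted(df.loc[df["marker_id"] == m, "allele"].unique())),
            )
            for m in marker_order
        ]
    groups = sorted(df["group"].unique())
    mi = {m: i for i, m in enumerate(loc.marker_id for loc in panel)}
    G, L = len(groups), len(panel)
    freqs = np.zeros((G, L, MAX_ALLELE))
    n_copies = np.zeros((G, L))
    for _, row in df.iterrows():
        g = groups.index(row["group"])
        li = mi[row["marker_id"]]
        freqs[g, li, int(row["allele"]) - 1] = row["frequency"]
        if "n_copies" in df.columns:
            n_copies[g, li] = row["n_copies"]
    return FrequencyTable(groups, list(panel), freqs, n_copies)


# ---------------------------------------------------------------------------
# STRUCTURE text format
# ---------------------------------------------------------------------------

def _tokenize(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        toks = raw.split()
        if not toks:
            continue
        if header is None:
            header = toks
        else:
            rows.append((lineno, toks))
    if header is None:
        raise FormatError(f"{path}: empty file (no header of marker names)")
    return header, rows


def _two_row_plausible(rows: list[tuple[int, list[str]]]) -> bool:
    """Structural check: even row count and paired rows share sample ids."""
    if len(rows) % 2:
        return False
    return all(
        t1 and t2 and t1[0] == t2[0]
        for (_, t1), (_, t2) in zip(rows[::2], rows[1::2])
    )


def _detect_layout(
    n_loci: int, rows: list[tuple[int, list[str]]], dialect: str
) -> tuple[str, int]:
    """Resolve dialect and metadata-column count from the data rows."""
    width = len(rows[0][1])
    one_meta = width - 2 * n_loci
    two_meta = width - n_loci
    if dialect == "one-row":
        if one_meta not in (2, 3):
            raise FormatError(
                f"one-row dialect: row width {width} incompatible with "
                f"{n_loci} loci (need 2 or 3 metadata columns)"
            )
        return "one-row", one_meta
    if dialect == "two-row":
        if two_meta not in (2, 3):
            raise FormatError(
                f"two-row dialect: row width {width} incompatible with "
                f"{n_loci} loci"
            )
        return "two-row", two_meta
    if dialect == "auto":
        one_ok = one_meta in (2, 3)
        two_ok = two_meta in (2, 3)
        if one_ok and two_ok:
            # widths alone are ambiguous (small panels); use row pairing:
            # the two-row layout repeats each individual's metadata
            if _two_row_plausible(rows):
                raise FormatError(
                    "ambiguous layout: pass dialect='one-row' or 'two-row'"
                )
            two_ok = False
        if one_ok and not two_ok:
            return "one-row", one_meta
        if two_ok and not one_ok:
            return "two-row", two_meta
        raise FormatError(
            f"row width {width} fits neither dialect for {n_loci} loci"
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def read_structure_file(
    path: str | Path,
    dialect: str = "auto",
    label_map: Mapping[str, str] | None = None,
    panel: Sequence[LocusDef] | None = None,
    has_popflag: bool | None = None,
) -> GenotypeTable:
    """Parse a STRUCTURE-format genotype file.

    Parameters
    ----------
    dialect:
        ``"one-row"`` (two adjacent columns per locus), ``"two-row"`` (one
        column per locus, two lines per individual) or ``"auto"``.
    label_map:
        Optional population-code -> continental-group map; unmapped codes
        keep their population label as group.
    panel:
        Optional locus definitions; defaults to loci inferred from the
        header, with allele codes taken from the observed data.
    has_popflag:
        Force presence/absence of the POPFLAG column; by default a third
        metadata column of 0/1 values is auto-detected.
    """
    path = Path(path)
    header, rows = _tokenize(path)
    n_loci = len(header)
    if not rows:
        dialect_resolved = "one-row" if dialect == "auto" else dialect
        panel_out = list(panel) if panel is not None else [
            LocusDef(m) for m in header
        ]
        samples = pd.DataFrame(
            columns=["sample_id", "population", "group", "popflag"]
        )
        return GenotypeTable(
            panel_out, samples, np.empty((0, n_loci, 2), dtype=np.int16)
        )

    dialect, n_meta = _detect_layout(n_loci, rows, dialect)
    if has_popflag is True and n_meta != 3:
        raise FormatError("popflag column requested but only 2 metadata columns")
    if has_popflag is False:
        n_meta = min(n_meta, 2)

    def parse_meta(toks: list[str], lineno: int) -> tuple[str, str, int]:
        sid, pop = toks[0], toks[1]
        flag = 0
        if n_meta == 3:
            try:
                flag = int(toks[2])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: popflag column is not an integer"
                ) from None
            if flag not in (0, 1):
                raise FormatError(f"line {lineno}: popflag must be 0 or 1")
        return sid, pop, flag

    def parse_alleles(toks: list[str], lineno: int) -> np.ndarray:
        try:
            return np.array([int(t) for t in toks], dtype=np.int16)
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-integer allele code"
            ) from None

    sample_rows = []
    calls_rows = []
    if dialect == "one-row":
        width = n_meta + 2 * n_loci
        for lineno, toks in rows:
            if len(toks) != width:
                raise FormatError(
                    f"line {lineno}: expected {width} columns, got {len(toks)}"
                )
            sid, pop, flag = parse_meta(toks, lineno)
            alleles = parse_alleles(toks[n_meta:], lineno)
            sample_rows.append((sid, pop, flag))
            calls_rows.append(alleles.reshape(n_loci, 2))
    else:
        if len(rows) % 2:
            raise FormatError(
                "two-row dialect: odd number of data lines "
                f"(line {rows[-1][0]} unpaired)"
            )
        width = n_meta + n_loci
        for (ln1, t1), (ln2, t2) in zip(rows[::2], rows[1::2]):
            for ln, t in ((ln1, t1), (ln2, t2)):
                if len(t) != width:
                    raise FormatError(
                        f"line {ln}: expected {width} columns, got {len(t)}"
                    )
            sid1, pop1, flag1 = parse_meta(t1, ln1)
            sid2, pop2, _ = parse_meta(t2, ln2)
            if sid1 != sid2 or pop1 != pop2:
                raise FormatError(
                    f"lines {ln1}/{ln2}: the two rows of individual "
                    f"{sid1!r} disagree on metadata"
                )
            a1 = parse_alleles(t1[n_meta:], ln1)
            a2 = parse_alleles(t2[n_meta:], ln2)
            sample_rows.append((sid1, pop1, flag1))
            calls_rows.append(np.stack([a1, a2], axis=1))

    calls = np.stack(calls_rows) if calls_rows else np.empty(
        (0, n_loci, 2), dtype=np.int16
    )

    # promote half-missing genotypes to fully missing
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        warnings.warn(
            f"{int(half.sum())} half-missing genotype(s) promoted to missing",
            stacklevel=2,
        )
        calls[half] = MISSING

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "population", "popflag"]
    )
    lm = dict(label_map or {})
    samples["group"] = samples["population"].map(lambda p: lm.get(p, p))
    samples = samples[["sample_id", "population", "group", "popflag"]]

    if panel is not None:
        panel_out = list(panel)
        if [p.marker_id for p in panel_out] != header:
            raise FormatError("panel marker ids do not match file header")
    else:
        panel_out = []
        for j, m in enumerate(header):
            obs = calls[:, j, :]
            codes = sorted(int(c) for c in np.unique(obs[obs != MISSING]))
            if len(codes) < 2:
                codes = sorted(set(codes) | {1, 2})
            panel_out.append(LocusDef(m, tuple(codes)))

    return GenotypeTable(panel_out, samples, calls)


def write_structure_file(
    table: GenotypeTable,
    path: str | Path,
    dialect: str = "one-row",
    include_popflag: bool | None = None,
) -> None:
    """Write a table in STRUCTURE text format (``MISSING`` -> ``-9``)."""
    if dialect not in ("one-row", "two-row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if include_popflag is None:
        include_popflag = bool((table.samples["popflag"] != 0).any())
    lines = [" ".join(table.marker_ids)]
    for i in range(table.n_individuals):
        row = table.samples.iloc[i]
        meta = [str(row["sample_id"]), str(row["population"])]
        if include_popflag:
            meta.append(str(int(row["popflag"])))
        if dialect == "one-row":
            alleles = " ".join(str(int(a)) for a in table.calls[i].ravel())
            lines.append(" ".join(meta) + " " + alleles if alleles else " ".join(meta))
        else:
            for slot in (0, 1):
                alleles = " ".join(
                    str(int(a)) for a in table.calls[i, :, slot]
                )
                lines.append(" ".join(meta) + " " + alleles)
    Path(path).write_text("\n".join(lines) + "\n")


def summarize(table: GenotypeTable) -> dict:
    """Basic cohort summary (counts and missing-call fraction)."""
    n, L = table.n_individuals, table.n_loci
    n_missing = int(table.missing_mask().sum())
    return {
        "n_individuals": n,
        "n_populations": int(table.samples["population"].nunique()),
        "n_groups": int(table.samples["group"].nunique()),
        "n_loci": L,
        "missing_call_fraction": (n_missing / (n * L)) if n * L else 0.0,
    }


def read_label_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (population, group) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label map needs two columns: population, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_panel_metadata() -> list[LocusDef]:
    """The 46-marker AIM-INDEL panel metadata shipped with the package.

    Positions are 1-based dbSNP build-132 coordinates.  The two markers with
    documented extra length variants (a third fragment size, coded allele 3)
    carry a note naming the variant background.
    """
    with resources.files("aimpanel.data").joinpath(
        "panel_metadata.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
    panel = []
    for _, r in df.iterrows():
        codes = tuple(int(c) for c in str(r["allele_codes"]).split(","))
        panel.append(
            LocusDef(
                marker_id=r["marker_id"],
                allele_codes=codes,
                rs_id=r["rs_id"],
                chromosome=str(r["chromosome"]),
                position_bp=int(r["position_bp"]),
                note="" if pd.isna(r["note"]) else str(r["note"]),
            )
        )
    return panel
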