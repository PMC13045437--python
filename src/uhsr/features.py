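"""Chemically-intuitive featurization for TLC structure-property modeling.

A measurement is described by 23 features: the volume fractions of the five
mobile-phase solvents (n-hexane, ethyl acetate, dichloromethane, methanol,
diethyl ether), counts of 16 representative functional groups, the number of
benzene rings and the dipole moment.  Functional-group and ring counts can be
derived from SMILES via RDKit substructure matching with exclusive priority
rules (a carbonyl carbon is counted once, as acid > ester > amide > aldehyde
> ketone), or consumed directly from the canonical CSV schema.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import SchemaError, SmilesParseError, ValidationError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Canonical solvent order (feature-vector positions 0..4 and CSV columns).
SOLVENT_NAMES = ("Hex", "EA", "DCM", "MeOH", "Et2O")

#: Canonical functional-group order (feature-vector positions 5..20).
FG_NAMES = (
    "CtPh", "CtOH", "CtAl", "CtCO2H", "CtRCO2R", "CtR2CO", "CtROR", "CtCN",
    "CtNH2", "CtNO2", "CtAm", "CtMe", "CtF", "CtCl", "CtBr", "CtI",
)

#: Canonical 23-feature order of the assembled vector.
FEATURE_NAMES = SOLVENT_NAMES + FG_NAMES + ("NBen", "DM")

SOLVENT_SLICE = slice(0, 5)
FG_SLICE = slice(5, 21)
NBEN_INDEX = 21
DM_INDEX = 22

#: Canonical CSV column order (header contract for read/write_dataset).
CSV_COLUMNS = ("id",) + SOLVENT_NAMES + ("NBen", "DM") + FG_NAMES + ("Rf",)

#: Published marginal means of the FG counts over the benchmark.
BENCHMARK_FG_MEANS = {
    "CtPh": 0.15, "CtOH": 0.04, "CtAl": 0.19, "CtCO2H": 0.03,
    "CtRCO2R": 0.10, "CtR2CO": 0.35, "CtROR": 0.17, "CtCN": 0.06,
    "CtNH2": 0.08, "CtNO2": 0.06, "CtAm": 0.02, "CtMe": 0.20,
    "CtF": 0.25, "CtCl": 0.11, "CtBr": 0.15, "CtI": 0.12,
}

#: Published marginal standard deviations of the FG counts.
BENCHMARK_FG_STDS = {
    "CtPh": 0.40, "CtOH": 0.21, "CtAl": 0.40, "CtCO2H": 0.18,
    "CtRCO2R": 0.32, "CtR2CO": 0.54, "CtROR": 0.47, "CtCN": 0.25,
    "CtNH2": 0.28, "CtNO2": 0.25, "CtAm": 0.14, "CtMe": 0.54,
    "CtF": 0.81, "CtCl": 0.39, "CtBr": 0.39, "CtI": 0.33,
}

#: Published marginals of the distribution features.
BENCHMARK_NBEN_MEAN, BENCHMARK_NBEN_STD = 1.12, 0.57
BENCHMARK_DM_MEAN, BENCHMARK_DM_STD = 1.34, 0.74

_SOLVENT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class SolventComposition:
    """Volume fractions of a (usually binary) mobile phase; sums to one."""

    hex: float = 0.0
    ea: float = 0.0
    dcm: float = 0.0
    meoh: float = 0.0
    et2o: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"solvent fraction {f.name}={v} outside [0, 1]"
                )
        s = self.hex + self.ea + self.dcm + self.meoh + self.et2o
        if abs(s - 1.0) > _SOLVENT_SUM_TOL:
            raise ValidationError(f"solvent fractions sum to {s}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.hex, self.ea, self.dcm, self.meoh, self.et2o])

    @classmethod
    def from_array(cls, a: Sequence[float], normalize: bool = False
                   ) -> "SolventComposition":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise SchemaError(f"expected 5 solvent fractions, got shape {a.shape}")
        if normalize:
            s = a.sum()
            if s <= 0:
                raise ValidationError("cannot normalize an all-zero composition")
            a = a / s
        return cls(*a.tolist())

    @classmethod
    def pure(cls, name: str) -> "SolventComposition":
        if name not in SOLVENT_NAMES:
            raise SchemaError(f"unknown solvent {name!r}")
        return cls.from_array(np.eye(5)[SOLVENT_NAMES.index(name)])


@dataclass(frozen=True)
class FGCounts:
    """Counts of the 16 representative functional groups."""

    ct_ph: int = 0
    ct_oh: int = 0
    ct_al: int = 0
    ct_co2h: int = 0
    ct_rco2r: int = 0
    ct_r2co: int = 0
    ct_ror: int = 0
    ct_cn: int = 0
    ct_nh2: int = 0
    ct_no2: int = 0
    ct_am: int = 0
    ct_me: int = 0
    ct_f: int = 0
    ct_cl: int = 0
    ct_br: int = 0
    ct_i: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(
                    f"functional-group count {f.name}={v!r} must be a "
                    "non-negative integer"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "FGCounts":
        a = np.asarray(a, dtype=float)
        if a.shape != (16,):
            raise SchemaError(f"expected 16 FG counts, got shape {a.shape}")
        if not np.allclose(a, np.round(a)):
            raise ValidationError("FG counts must be integral")
        return cls(*(int(round(v)) for v in a))


@dataclass(frozen=True)
class SoluteDescriptors:
    """18-dimensional solute description: FG counts + ring count + dipole."""

    fg: FGCounts = field(default_factory=FGCounts)
    n_ben: int = 0
    dm: float = 0.0

    def __post_init__(self):
        if not (isinstance(self.n_ben, (int, np.integer)) and self.n_ben >= 0):
            raise ValidationError(f"n_ben={self.n_ben!r} must be a non-negative integer")
        if not (self.dm >= 0 and math.isfinite(self.dm)):
            raise ValidationError(f"dm={self.dm!r} must be a finite non-negative real")


@dataclass(frozen=True)
class TLCRecord:
    """One TLC measurement: solvent system, solute, and (optionally) Rf."""

    solvent: SolventComposition
    solute: SoluteDescriptors
    rf: Optional[float] = None
    id: str = ""

    def __post_init__(self):
        if self.rf is not None and not (0.0 <= self.rf <= 1.0):
            raise ValidationError(f"rf={self.rf} outside [0, 1]")


# ---------------------------------------------------------------------------
# Substructure counting
# ---------------------------------------------------------------------------

# Carbonyl-carbon patterns, in exclusive priority order.  Each carbonyl carbon
# is claimed by the first pattern that matches it.
_CARBONYL_PRIORITY = (
    ("ct_co2h", "[CX3](=O)[OX2H1]"),
    ("ct_rco2r", "[CX3](=O)[OX2H0][#6]"),
    ("ct_am", "[CX3](=O)[NX3]"),
    ("ct_al", "[CX3H1]=O"),
    ("ct_r2co", "[#6][CX3](=O)[#6]"),
)

# Independent patterns (exclusions encoded in the SMARTS themselves).
_SIMPLE_PATTERNS = {
    "ct_ph": "[OX2H1][c]",                       # hydroxyl on aromatic carbon
    "ct_oh": "[OX2H1][CX4]",                     # hydroxyl on sp3 carbon
    "ct_ror": "[OD2;!$([OD2]C=O)]([#6])[#6]",    # ether O, ester O excluded
    "ct_cn": "[CX2]#[NX1]",
    "ct_nh2": "[NX3;H2;!$(NC=O)][#6]",           # primary amine, amide N excluded
    "ct_no2": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "ct_me": "[CX4H3;D1]",                       # CH3 bonded to one heavy atom
    "ct_f": "[F]",
    "ct_cl": "[Cl]",
    "ct_br": "[Br]",
    "ct_i": "[I]",
}

_compiled_carbonyl = [(k, Chem.MolFromSmarts(s)) for k, s in _CARBONYL_PRIORITY]
_compiled_simple = {k: Chem.MolFromSmarts(s) for k, s in _SIMPLE_PATTERNS.items()}


def _mol_from_smiles(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise SmilesParseError(structure)
    return mol


def count_functional_groups(structure: str) -> FGCounts:
    """Count the 16 functional groups in a SMILES string.

    Carbonyl-bearing groups are matched with exclusive priority
    (acid > ester > amide > aldehyde > ketone) so each carbonyl carbon
    contributes to exactly one count.  Deterministic and invariant to the
    SMILES atom ordering of the same molecule.
    """
    mol = _mol_from_smiles(structure)
    counts = {f.name: 0 for f in fields(FGCounts)}

    claimed: set[int] = set()  # carbonyl carbons already assigned to a group
    for key, pat in _compiled_carbonyl:
        carbons = {m[0] for m in mol.GetSubstructMatches(pat)}
        if key == "ct_r2co":
            # ketone SMARTS puts the carbonyl carbon second
            carbons = {m[1] for m in mol.GetSubstructMatches(pat)}
        fresh = carbons - claimed
        counts[key] = len(fresh)
        claimed |= fresh

    for key, pat in _compiled_simple.items():
        counts[key] = len({m[0] for m in mol.GetSubstructMatches(pat)})

    return FGCounts(**counts)


def count_benzene_rings(structure: str) -> int:
    """Number of six-membered carbocyclic aromatic rings (fused rings each count)."""
    mol = _mol_from_smiles(structure)
    n = 0
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms):
            n += 1
    return n


def featurize_smiles(structure: str, dm: float = 0.0) -> SoluteDescriptors:
    """Derive the 18 solute descriptors from a SMILES string.

    The dipole moment is a provided numeric value, never computed here.
    """
    return SoluteDescriptors(
        fg=count_functional_groups(structure),
        n_ben=count_benzene_rings(structure),
        dm=float(dm),
    )


# ---------------------------------------------------------------------------
# Feature assembly and dataset IO
# ---------------------------------------------------------------------------

def assemble_features(record: TLCRecord) -> np.ndarray:
    """Assemble the canonical 23-vector [solvent(5) | fg(16) | NBen | DM]."""
    return np.concatenate([
        record.solvent.as_array(),
        record.solute.fg.as_array(),
        [float(record.solute.n_ben), float(record.solute.dm)],
    ])


def features_matrix(records: Sequence[TLCRecord]) -> np.ndarray:
    """Stack assembled feature vectors into an (n, 23) matrix."""
    return np.stack([assemble_features(r) for r in records])


def rf_vector(records: Sequence[TLCRecord]) -> np.ndarray:
    """Observed Rf values; raises if any record lacks one."""
    rf = [r.rf for r in records]
    if any(v is None for v in rf):
        raise ValidationError("record without an observed Rf value")
    return np.asarray(rf, dtype=float)


def record_from_features(x: Sequence[float], rf: Optional[float] = None,
                         id: str = "", normalize_solvent: bool = False
                         ) -> TLCRecord:
    """Inverse of :func:`assemble_features`."""
    x = np.asarray(x, dtype=float)
    if x.shape != (23,):
        raise SchemaError(f"expected a 23-feature vector, got shape {x.shape}")
    return TLCRecord(
        solvent=SolventComposition.from_array(x[SOLVENT_SLICE],
                                              normalize=normalize_solvent),
        solute=SoluteDescriptors(
            fg=FGCounts.from_array(x[FG_SLICE]),
            n_ben=int(round(x[NBEN_INDEX])),
            dm=float(x[DM_INDEX]),
        ),
        rf=rf,
        id=id,
    )


def records_to_frame(records: Sequence[TLCRecord]) -> pd.DataFrame:
    """Render records as a DataFrame in the canonical CSV column order."""
    rows = []
    for r in records:
        x = assemble_features(r)
        row = {"id": r.id}
        row.update({n: x[SOLVENT_SLICE][i] for i, n in enumerate(SOLVENT_NAMES)})
        row["NBen"] = int(round(x[NBEN_INDEX]))
        row["DM"] = x[DM_INDEX]
        row.update({n: int(x[FG_SLICE][i]) for i, n in enumerate(FG_NAMES)})
        row["Rf"] = np.nan if r.rf is None else r.rf
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame, solvent_mode: str = "strict"
                     ) -> list[TLCRecord]:
    """Validate a canonical-schema DataFrame into records.

    solvent_mode:
        "strict"     reject rows whose solvent fractions do not sum to 1;
        "normalize"  rescale fractions to sum 1 (logged).
    """
    if solvent_mode not in ("strict", "normalize"):
        raise SchemaError(f"unknown solvent_mode {solvent_mode!r}")
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "Rf"]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")
    has_rf = "Rf" in df.columns

    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            solvent = SolventComposition.from_array(
                [row[n] for n in SOLVENT_NAMES],
                normalize=(solvent_mode == "normalize"),
            )
            if solvent_mode == "normalize":
                raw_sum = float(sum(row[n] for n in SOLVENT_NAMES))
                if abs(raw_sum - 1.0) > _SOLVENT_SUM_TOL:
                    logger.warning(
                        "row %d: solvent fractions sum to %.4f, renormalized",
                        pos, raw_sum,
                    )
            rf = None
            if has_rf and not pd.isna(row["Rf"]):
                rf = float(row["Rf"])
            rec = TLCRecord(
                solvent=solvent,
                solute=SoluteDescriptors(
                    fg=FGCounts.from_array([row[n] for n in FG_NAMES]),
                    n_ben=int(row["NBen"]),
                    dm=float(row["DM"]),
                ),
                rf=rf,
                id=str(row["id"]),
            )
        except (ValidationError, SchemaError) as exc:
            raise type(exc)(f"row {pos}: {exc}") from exc
        records.append(rec)
    return records


def read_dataset(path, solvent_mode: str = "strict") -> list[TLCRecord]:
    """Read a canonical-schema CSV into validated records."""
    df = pd.read_csv(path)
    return frame_to_records(df, solvent_mode=solvent_mode)


def write_dataset(records: Sequence[TLCRecord], path) -> None:
    """Write records as a canonical-schema CSV (lossless round-trip)."""
    records_to_frame(records).to_csv(path, index=False)


def read_smiles_dataset(path, solvent_mode: str = "strict") -> list[TLCRecord]:
    """Read a CSV of `id,smiles,DM` + solvent columns (+ optional Rf),
    deriving FG and ring counts from the SMILES."""
    df = pd.read_csv(path)
    needed = ["id", "smiles", "DM", *SOLVENT_NAMES]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            solvent = SolventComposition.from_array(
                [row[n] for n in SOLVENT_NAMES],
                normalize=(solvent_mode == "normalize"),
            )
            solute = featurize_smiles(str(row["smiles"]), dm=float(row["DM"]))
            rf = None
            if "Rf" in df.columns and not pd.isna(row["Rf"]):
                rf = float(row["Rf"])
            records.append(TLCRecord(solvent=solvent, solute=solute, rf=rf,
                                     id=str(row["id"])))
        except SmilesParseError as exc:
            raise SmilesParseError(f"{exc.smiles} (row {pos})") from exc
        except (ValidationError, SchemaError) as exc:
            raise type(exc)(f"row {pos}: {exc}") from exc
    return records
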