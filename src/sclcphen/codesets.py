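"""Medical code sets and matching.

Every predicate in the pipeline — lung-cancer diagnosis capture, the
registry gold standard, and all treatment-exposure flags — is a membership
test of a (code, coding-system) pair against a named :class:`CodeSet`.
Four coding systems are supported: HCPCS/CPT procedure and drug-administration
codes, NDC drug-product codes, ICD-10-CM diagnosis codes, and ICD-O-3
histology codes. Systems are never compared across each other: a code only
matches a set of the same system.

The built-in registry ships the code sets the pipeline needs out of the box.
The ICD-O-3 small-cell histology set (8002, 8041-8045) and the EGFR-testing
CPT code (81235) are the published definitions; the per-drug HCPCS J-codes
are representative placeholders (real studies substitute their full HCPCS/NDC
lists via :func:`load_codesets`). The synthetic generator draws its claim
codes from this same registry, so the pipeline is closed and internally
consistent regardless of placeholder realism.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class CodeSystem(str, enum.Enum):
    """Coding system of a claim code or code set."""

    HCPCS_CPT = "HCPCS_CPT"
    NDC = "NDC"
    ICD10CM_DX = "ICD10CM_DX"
    ICDO3_HIST = "ICDO3_HIST"


def normalize_code(code: str, system: CodeSystem) -> str:
    """Canonical form of a code: uppercase, whitespace-stripped.

    ICD-10-CM codes are additionally dot-insensitive ("C34.12" == "C3412");
    NDC codes are hyphen-insensitive with leading zeros stripped (the only
    NDC normalization performed).
    """
    c = str(code).strip().upper()
    if system is CodeSystem.ICD10CM_DX:
        c = c.replace(".", "")
    elif system is CodeSystem.NDC:
        c = c.replace("-", "").lstrip("0")
    return c


@dataclass(frozen=True)
class CodeSet:
    """A named set of codes within one coding system.

    ``match_mode`` is either ``"exact"`` or ``"prefix"``; prefix matching is
    only permitted for ICD-10-CM diagnosis sets (e.g. the C34 lung-cancer
    family).
    """

    name: str
    system: CodeSystem
    codes: frozenset[str]
    match_mode: str = "exact"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("code set needs a name")
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"{self.name}: unknown match_mode {self.match_mode!r}")
        if self.match_mode == "prefix" and self.system is not CodeSystem.ICD10CM_DX:
            raise ValueError(f"{self.name}: prefix matching is only allowed for ICD10CM_DX")
        norm = frozenset(normalize_code(c, self.system) for c in self.codes)
        if not norm or "" in norm:
            raise ValueError(f"{self.name}: codes must be non-empty")
        object.__setattr__(self, "codes", norm)

    def match(self, code: str, system: CodeSystem | str) -> bool:
        """True iff *code* in *system* belongs to this set."""
        system = CodeSystem(system)
        if system is not self.system:
            return False
        c = normalize_code(code, self.system)
        if not c:
            return False
        if self.match_mode == "exact":
            return c in self.codes
        return any(c.startswith(p) for p in self.codes)


def match(code: str, system: CodeSystem | str, codeset: CodeSet) -> bool:
    """Functional form of :meth:`CodeSet.match`."""
    return codeset.match(code, system)


@dataclass
class CodeSetRegistry:
    """Mapping from code-set name to :class:`CodeSet` with unique names."""

    entries: dict[str, CodeSet] = field(default_factory=dict)

    def add(self, cs: CodeSet, replace: bool = False) -> None:
        if cs.name in self.entries and not replace:
            raise ValueError(f"duplicate code set name {cs.name!r}")
        self.entries[cs.name] = cs

    def __getitem__(self, name: str) -> CodeSet:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"unknown code set {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)


#: Code sets that count as outpatient systemic therapy (antineoplastic agents
#: and their supportive G-CSF companions are listed individually; the union
#: sets ``platinum`` and ``gcsf`` are derived, and fosaprepitant / EGFR testing
#: are deliberately excluded — an antiemetic or a molecular test does not make
#: a patient "treated").
SYSTEMIC_THERAPY_SETS: tuple[str, ...] = (
    "carboplatin",
    "cisplatin",
    "oxaliplatin",
    "etoposide",
    "filgrastim",
    "pegfilgrastim",
    "nivolumab",
    "ipilimumab",
    "irinotecan",
    "topotecan",
)

# Representative HCPCS J-codes, placeholders for full study code lists.
_DRUG_PLACEHOLDERS: dict[str, str] = {
    "carboplatin": "J9045",
    "cisplatin": "J9060",
    "oxaliplatin": "J9263",
    "etoposide": "J9181",
    "filgrastim": "J1442",
    "pegfilgrastim": "J2505",
    "nivolumab": "J9299",
    "ipilimumab": "J9228",
    "irinotecan": "J9206",
    "topotecan": "J9351",
    "fosaprepitant": "J1453",
}

#: Union sets recomputed from their components whenever components change.
UNION_SETS: dict[str, tuple[str, ...]] = {
    "platinum": ("carboplatin", "cisplatin", "oxaliplatin"),
    "gcsf": ("filgrastim", "pegfilgrastim"),
}


def _rebuild_unions(reg: CodeSetRegistry, keep: Iterable[str] = ()) -> None:
    keep = set(keep)
    for union_name, parts in UNION_SETS.items():
        if union_name in keep:
            continue  # explicitly (re)defined by the caller; leave alone
        systems = {reg[p].system for p in parts}
        if len(systems) != 1:
            raise ValueError(f"{union_name}: component sets span multiple systems")
        codes = frozenset().union(*(reg[p].codes for p in parts))
        reg.add(
            CodeSet(union_name, systems.pop(), codes, match_mode="exact"),
            replace=True,
        )


def builtin_registry() -> CodeSetRegistry:
    """Registry of built-in code sets.

    Contains the lung-cancer ICD-10 family (prefix C34, dot-insensitive), the
    six ICD-O-3 small-cell histology codes, one placeholder HCPCS code per
    systemic-therapy agent, the fosaprepitant antiemetic, the EGFR-testing CPT
    code 81235, and the two union sets ``platinum`` (carboplatin ∪ cisplatin ∪
    oxaliplatin) and ``gcsf`` (filgrastim ∪ pegfilgrastim).
    """
    reg = CodeSetRegistry()
    reg.add(CodeSet("lung_cancer_dx", CodeSystem.ICD10CM_DX, frozenset({"C34"}), "prefix"))
    reg.add(
        CodeSet(
            "sclc_histology",
            CodeSystem.ICDO3_HIST,
            frozenset({"8002", "8041", "8042", "8043", "8044", "8045"}),
        )
    )
    for drug, jcode in _DRUG_PLACEHOLDERS.items():
        reg.add(CodeSet(drug, CodeSystem.HCPCS_CPT, frozenset({jcode})))
    reg.add(CodeSet("egfr_test", CodeSystem.HCPCS_CPT, frozenset({"81235"})))
    _rebuild_unions(reg)
    return reg


_FILE_COLUMNS = ("set_name", "system", "code", "match_mode")


def load_codesets(path: str | Path) -> CodeSetRegistry:
    """Load a CSV code-set file and merge it over the built-in registry.

    Format: UTF-8 CSV with header ``set_name,system,code,match_mode``, one row
    per code. A file entry whose name collides with a built-in replaces that
    built-in set wholesale; built-in union sets are recomputed from their
    (possibly overridden) components unless the file defines the union itself.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is not None:
            missing = [c for c in _FILE_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise ValueError(f"{path}: missing columns {missing} in header")
        for lineno, row in enumerate(reader, start=2):
            name = (row.get("set_name") or "").strip()
            sys_label = (row.get("system") or "").strip()
            code = (row.get("code") or "").strip()
            mode = (row.get("match_mode") or "exact").strip() or "exact"
            if not name or not code:
                raise ValueError(f"{path}:{lineno}: set_name and code are required")
            try:
                system = CodeSystem(sys_label)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown system {sys_label!r} "
                    f"(expected one of {[s.value for s in CodeSystem]})"
                ) from None
            entry = rows.setdefault(name, {"system": system, "mode": mode, "codes": set()})
            if entry["system"] is not system:
                raise ValueError(f"{path}:{lineno}: set {name!r} mixes coding systems")
            if entry["mode"] != mode:
                raise ValueError(f"{path}:{lineno}: set {name!r} mixes match modes")
            entry["codes"].add(code)

    reg = builtin_registry()
    for name, entry in rows.items():
        reg.add(
            CodeSet(name, entry["system"], frozenset(entry["codes"]), entry["mode"]),
            replace=True,
        )
    _rebuild_unions(reg, keep=rows.keys())
    return reg


def write_codesets(reg: CodeSetRegistry, path: str | Path) -> None:
    """Write every set of *reg* in the CSV code-set file format."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FILE_COLUMNS)
        for name in sorted(reg.names()):
            cs = reg[name]
            for code in sorted(cs.codes):
                writer.writerow([name, cs.system.value, code, cs.match_mode])


def systemic_therapy_union(reg: CodeSetRegistry) -> Mapping[CodeSystem, frozenset[str]]:
    """Per-system union of all systemic-therapy codes (for the treated flag)."""
    out: dict[CodeSystem, set[str]] = {}
    for name in SYSTEMIC_THERAPY_SETS:
        if name not in reg:
            continue
        cs = reg[name]
        out.setdefault(cs.system, set()).update(cs.codes)
    return {k: frozenset(v) for k, v in out.items()}
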