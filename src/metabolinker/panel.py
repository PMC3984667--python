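"""Targeted serum metabolite panel definitions.

The quantification kit emulated here measures 163 metabolites in five
biochemical classes: 41 acylcarnitines, 14 amino acids, one sugar
(hexose), 92 glycerophospholipids (diacyl- and acyl-alkyl-
phosphatidylcholines plus lyso-phosphatidylcholines) and 15
sphingolipids.  The short names follow the field's conventions
("PC aa C42:1", "lysoPC a C18:1", "SM (OH) C22:1", "C14", ...), so class
membership can be recovered from the name alone.

The metabolite identities generated here are a synthetic stand-in for the
commercial panel's analyte list: class counts and naming conventions
match, individual lipid species are enumerated systematically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: class label -> number of panel members
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "acylcarnitine": 41,
    "amino acid": 14,
    "sugar": 1,
    "glycerophospholipid": 92,
    "sphingolipid": 15,
}

#: split of the 92 glycerophospholipids into subclasses
GLYCEROPHOSPHOLIPID_SPLIT: dict[str, int] = {
    "PC aa": 39,
    "PC ae": 38,
    "lysoPC": 15,
}

_AMINO_ACIDS = [
    "Ala", "Arg", "Gln", "Gly", "His", "Met", "Orn", "Phe",
    "Pro", "Ser", "Thr", "Trp", "Tyr", "xLeu",
]


@dataclass(frozen=True)
class PanelSpec:
    """Composition of the targeted panel, as class -> member count."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )

    def __post_init__(self) -> None:
        for cls, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def metabolite_class(short_name: str) -> str:
    """Infer the biochemical class (and PC subclass) from a short name.

    Returns one of ``acylcarnitine``, ``amino acid``, ``sugar``,
    ``PC aa``, ``PC ae``, ``lysoPC``, ``sphingolipid``.
    """
    name = short_name.strip()
    if name.startswith("PC aa"):
        return "PC aa"
    if name.startswith("PC ae"):
        return "PC ae"
    if name.startswith("lysoPC"):
        return "lysoPC"
    if name.startswith("SM"):
        return "sphingolipid"
    if name.startswith("C") and len(name) > 1 and name[1].isdigit():
        return "acylcarnitine"
    if name in ("H1", "Hexose"):
        return "sugar"
    return "amino acid"


_KNOWN_ACYLCARNITINES = [
    "C0", "C2", "C3", "C4", "C5", "C6", "C8", "C10", "C12", "C14",
    "C14:1", "C16", "C18", "C18:1",
]


def _acylcarnitine_names(n: int) -> list[str]:
    # free carnitine, even-chain esters, unsaturated and hydroxylated
    # variants, as in targeted acylcarnitine panels
    names = list(_KNOWN_ACYLCARNITINES)[:n]
    for chain in range(3, 20):
        for suffix in ("", ":1", ":2", "-OH"):
            cand = f"C{chain}{suffix}"
            if len(names) == n:
                return names
            if cand not in names:
                names.append(cand)
    raise ValueError(f"cannot enumerate {n} acylcarnitines")


# species reported for this panel in the field's literature; the fill
# enumeration below completes the class counts with plausible neighbors
_KNOWN_PC_AA = [
    "PC aa C34:1", "PC aa C36:3", "PC aa C36:4", "PC aa C38:4",
    "PC aa C38:5", "PC aa C40:2", "PC aa C40:3", "PC aa C40:4",
    "PC aa C40:5", "PC aa C42:1", "PC aa C42:2", "PC aa C42:5",
    "PC aa C42:6",
]
_KNOWN_PC_AE = [
    "PC ae C36:0", "PC ae C38:1", "PC ae C38:3", "PC ae C40:4",
    "PC ae C40:5", "PC ae C42:0", "PC ae C42:1", "PC ae C42:2",
    "PC ae C44:3", "PC ae C44:4",
]
_KNOWN_LYSOPC = ["lysoPC a C16:1", "lysoPC a C18:1"]


def _pc_names(prefix: str, n: int) -> list[str]:
    names = list(_KNOWN_PC_AA if prefix == "PC aa" else _KNOWN_PC_AE)[:n]
    for carbons in range(28, 60, 2):
        for db in range(0, 7):
            cand = f"{prefix} C{carbons}:{db}"
            if len(names) == n:
                return names
            if cand not in names:
                names.append(cand)
    raise ValueError(f"cannot enumerate {n} {prefix} species")


def _lysopc_names(n: int) -> list[str]:
    names = list(_KNOWN_LYSOPC)[:n]
    for carbons in range(14, 30):
        for db in range(0, 2):
            cand = f"lysoPC a C{carbons}:{db}"
            if len(names) == n:
                return names
            if cand not in names:
                names.append(cand)
    raise ValueError(f"cannot enumerate {n} lysoPC species")


def _sphingolipid_names(n: int) -> list[str]:
    names = []
    for carbons in range(16, 28):
        for variant in (f"SM C{carbons}:1", f"SM (OH) C{carbons}:1"):
            names.append(variant)
            if len(names) == n:
                return names
    raise ValueError(f"cannot enumerate {n} sphingolipid species")


def build_panel(spec: PanelSpec | None = None) -> pd.DataFrame:
    """Enumerate the panel as a DataFrame with columns
    ``metabolite`` (unique short name) and ``class``.

    Under the default :class:`PanelSpec` this yields exactly 163 rows.
    """
    spec = spec or PanelSpec()
    rows: list[tuple[str, str]] = []
    for cls, count in spec.class_counts.items():
        if cls == "acylcarnitine":
            names = _acylcarnitine_names(count)
        elif cls == "amino acid":
            if count > len(_AMINO_ACIDS):
                names = _AMINO_ACIDS + [
                    f"AA{i}" for i in range(count - len(_AMINO_ACIDS))
                ]
            else:
                names = _AMINO_ACIDS[:count]
        elif cls == "sugar":
            names = ["H1"][:count]
        elif cls == "glycerophospholipid":
            split = _scaled_split(count)
            names = (
                _pc_names("PC aa", split["PC aa"])
                + _pc_names("PC ae", split["PC ae"])
                + _lysopc_names(split["lysoPC"])
            )
        elif cls == "sphingolipid":
            names = _sphingolipid_names(count)
        else:
            names = [f"{cls}_{i}" for i in range(count)]
        rows.extend((name, cls) for name in names)
    panel = pd.DataFrame(rows, columns=["metabolite", "class"])
    if panel["metabolite"].duplicated().any():
        dupes = panel.loc[panel["metabolite"].duplicated(), "metabolite"]
        raise ValueError(f"duplicate metabolite names: {sorted(set(dupes))}")
    return panel


def _scaled_split(total: int) -> dict[str, int]:
    """Split a glycerophospholipid count over PC aa / PC ae / lysoPC,
    keeping the default proportions."""
    if total == sum(GLYCEROPHOSPHOLIPID_SPLIT.values()):
        return dict(GLYCEROPHOSPHOLIPID_SPLIT)
    base = sum(GLYCEROPHOSPHOLIPID_SPLIT.values())
    split = {
        k: (v * total) // base for k, v in GLYCEROPHOSPHOLIPID_SPLIT.items()
    }
    # distribute remainder deterministically
    for k in GLYCEROPHOSPHOLIPID_SPLIT:
        if sum(split.values()) == total:
            break
        split[k] += 1
    return split
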