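"""Compound library annotation manifest.

The default manifest emulates a 330-compound annotated anti-cancer
repurposing library: every entry carries a parent drug and a mechanism
class, and a few drugs appear twice as alternative salt formulations
(e.g. topotecan / topotecan hydrochloride), which hit calling later
collapses to unique drug treatments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MANIFEST_COLUMNS = ["compound_id", "parent_drug", "mechanism_class", "is_salt_form"]

MECHANISM_CLASSES = [
    "proteasome inhibitor",
    "topoisomerase I inhibitor",
    "topoisomerase II inhibitor",
    "DNA synthesis inhibitor",
    "aldehyde dehydrogenase inhibitor",
    "kinase inhibitor",
    "HDAC inhibitor",
    "microtubule inhibitor",
    "antimetabolite",
    "PARP inhibitor",
]

# drugs named in the screened library, with their annotated mechanism;
# the four salt-form entries pair up to two parent drugs
_NAMED_DRUGS: list[tuple[str, str, str, bool]] = [
    ("C101", "topotecan", "topoisomerase I inhibitor", False),
    ("C102", "topotecan", "topoisomerase I inhibitor", True),   # topotecan HCl
    ("C201", "ixazomib", "proteasome inhibitor", False),
    ("C202", "ixazomib", "proteasome inhibitor", True),         # ixazomib citrate
    ("C011", "bortezomib", "proteasome inhibitor", False),
    ("C012", "carfilzomib", "proteasome inhibitor", False),
    ("C021", "irinotecan", "topoisomerase I inhibitor", False),
    ("C022", "10-hydroxycamptothecin", "topoisomerase I inhibitor", False),
    ("C031", "doxorubicin", "topoisomerase II inhibitor", False),
    ("C032", "daunorubicin", "topoisomerase II inhibitor", False),
    ("C033", "epirubicin", "topoisomerase II inhibitor", False),
    ("C034", "mitoxantrone", "topoisomerase II inhibitor", False),
    ("C035", "pixantrone", "topoisomerase II inhibitor", False),
    ("C041", "cytarabine", "DNA synthesis inhibitor", False),
    ("C042", "gemcitabine", "DNA synthesis inhibitor", False),
    ("C051", "disulfiram", "aldehyde dehydrogenase inhibitor", False),
]

SALT_PAIR_COMPOUNDS = ("C101", "C102", "C201", "C202")


def default_library_manifest(n_compounds: int = 330) -> pd.DataFrame:
    """Deterministic manifest for the default 330-compound library.

    Named, mechanistically annotated drugs occupy their fixed compound ids;
    the remaining entries are generic annotated compounds cycling over the
    mechanism classes.  Contains two salt-form pairs (topotecan and
    ixazomib formulations).
    """
    named = {cid: (drug, mech, salt) for cid, drug, mech, salt in _NAMED_DRUGS}
    rows = []
    generic_no = 0
    for i in range(n_compounds):
        cid = f"C{i + 1:03d}"
        if cid in named:
            drug, mech, salt = named[cid]
        else:
            generic_no += 1
            drug = f"compound_{generic_no:03d}"
            mech = MECHANISM_CLASSES[generic_no % len(MECHANISM_CLASSES)]
            salt = False
        rows.append((cid, drug, mech, salt))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Enforce manifest invariants; raises ValueError on violation."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest["compound_id"].duplicated().any():
        dups = manifest.loc[manifest["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound ids: {dups}")
    salts = manifest[manifest["is_salt_form"].astype(bool)]
    counts = manifest["parent_drug"].value_counts()
    for _, row in salts.iterrows():
        if counts[row["parent_drug"]] < 2:
            raise ValueError(
                f"salt form {row['compound_id']} has no sibling sharing "
                f"parent drug {row['parent_drug']!r}"
            )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path)
    out["is_salt_form"] = out["is_salt_form"].astype(bool)
    validate_manifest(out)
    return out
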