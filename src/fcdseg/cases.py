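"""Case collections: (case_id, image path, mask path) triples plus a
delimited-text manifest, the handover format between the phantom generator,
the preprocessing/selection pipeline and the cross-validation harness."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["Case", "CaseCollection"]


@dataclass(frozen=True)
class Case:
    case_id: str
    image: Path
    mask: Path


@dataclass
class CaseCollection:
    """An ordered set of cases with unique ids and readable files."""

    cases: tuple[Case, ...]
    provenance: str = "external"  # synthetic | external
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cases = tuple(self.cases)
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids must be unique")
        for c in self.cases:
            for p in (c.image, c.mask):
                if not Path(p).exists():
                    raise FileNotFoundError(f"case {c.case_id}: missing file {p}")

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    def to_manifest(self, path) -> None:
        """Write a TSV manifest (paths relative to the manifest's directory)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        root = path.parent
        rows = pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "image": [_relativize(c.image, root) for c in self.cases],
                "mask": [_relativize(c.mask, root) for c in self.cases],
            }
        )
        if self.extra is not None:
            rows = rows.merge(self.extra, on="case_id", how="left")
        rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_manifest(cls, path, provenance: str | None = None) -> "CaseCollection":
        path = Path(path)
        table = pd.read_csv(path, sep="\t")
        root = path.parent
        cases = tuple(
            Case(str(r.case_id), root / str(r.image), root / str(r.mask))
            for r in table.itertuples()
        )
        extra_cols = [c for c in table.columns if c not in ("image", "mask")]
        extra = table[extra_cols] if len(extra_cols) > 1 else None
        return cls(cases=cases, provenance=provenance or "external", extra=extra)


def _relativize(p, root: Path) -> str:
    p = Path(p)
    try:
        return str(p.relative_to(root))
    except ValueError:
        return str(p)
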