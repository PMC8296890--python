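"""Structural-alert library: SMARTS patterns flagging reactive-metabolite liabilities.

A structural alert is a substructure whose presence in a drug suggests the
molecule can be bioactivated into an electrophilic (protein-reactive)
metabolite — the proposed trigger of drug-induced autoimmunity. Alerts are
stored as SMARTS patterns; the packaged builtin library covers the
nitrogen-containing-benzene family (aromatic amines by N-H count) and the
other high-frequency reactive-metabolite motifs (alkenes, benzylic halides,
phenols, halogenated carbons, methoxy/methyl arenes), plus the decomposed
"any nitrogen" and "benzene" patterns used for mechanistic comparison.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from rdkit import Chem

from .errors import FormatError, PatternError

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("alert_id", "smarts", "description")


@dataclass
class AlertPattern:
    """One structural alert: a named, documented SMARTS substructure query.

    Parameters
    ----------
    alert_id : str
        Unique identifier within a library.
    smarts : str
        Daylight-style SMARTS pattern; must compile under RDKit's default
        aromaticity model.
    description : str
        Human-readable account of the substructure (non-empty).
    family : str, optional
        Tag grouping related variants, e.g. the aromatic-amine N-H-count
        family.
    source : str, optional
        Provenance note.
    """

    alert_id: str
    smarts: str
    description: str
    family: str | None = None
    source: str | None = None
    _query: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.alert_id:
            raise PatternError("alert_id must be non-empty")
        if not self.description:
            raise PatternError(
                f"alert {self.alert_id!r}: description must be non-empty",
                (self.alert_id,),
            )
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise PatternError(
                f"alert {self.alert_id!r}: SMARTS {self.smarts!r} does not compile",
                (self.alert_id,),
            )
        self._query = query

    @property
    def query(self) -> Chem.Mol:
        """The compiled RDKit substructure query."""
        assert self._query is not None
        return self._query


class AlertLibrary:
    """Ordered, id-unique collection of :class:`AlertPattern`.

    Iteration order is the insertion (file) order and is stable.
    """

    def __init__(self, alerts: list[AlertPattern], name: str = "", version: str = ""):
        seen: set[str] = set()
        for alert in alerts:
            if alert.alert_id in seen:
                raise PatternError(
                    f"duplicate alert_id {alert.alert_id!r}", (alert.alert_id,)
                )
            seen.add(alert.alert_id)
        self._alerts = list(alerts)
        self._by_id = {a.alert_id: a for a in self._alerts}
        self.name = name
        self.version = version

    def __iter__(self) -> Iterator[AlertPattern]:
        return iter(self._alerts)

    def __len__(self) -> int:
        return len(self._alerts)

    def __getitem__(self, alert_id: str) -> AlertPattern:
        return self._by_id[alert_id]

    def __contains__(self, alert_id: str) -> bool:
        return alert_id in self._by_id

    @property
    def alert_ids(self) -> list[str]:
        return [a.alert_id for a in self._alerts]

    def subset(self, alert_ids: list[str]) -> "AlertLibrary":
        """A new library restricted to ``alert_ids``, in the given order."""
        return AlertLibrary([self[a] for a in alert_ids], name=self.name, version=self.version)


def load_alert_library(path: str | Path, name: str | None = None) -> AlertLibrary:
    """Load an alert library from a CSV file.

    The file must carry the header columns ``alert_id,smarts,description``;
    ``family`` and ``source`` are optional. Records are validated on load:
    a missing column raises :class:`FormatError`, and unparsable SMARTS
    raise :class:`PatternError` listing every offending ``alert_id``.
    An empty file (header only) yields an empty library with a warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        alerts: list[AlertPattern] = []
        bad: list[str] = []
        for row in reader:
            try:
                alerts.append(
                    AlertPattern(
                        alert_id=row["alert_id"],
                        smarts=row["smarts"],
                        description=row["description"],
                        family=row.get("family") or None,
                        source=row.get("source") or None,
                    )
                )
            except PatternError:
                bad.append(row.get("alert_id") or f"<row {reader.line_num}>")
    if bad:
        raise PatternError(
            f"{path}: {len(bad)} record(s) with invalid SMARTS or fields: {bad}",
            tuple(bad),
        )
    if not alerts:
        logger.warning("%s: alert library is empty (header only)", path)
    return AlertLibrary(alerts, name=name or path.stem)


def builtin_alerts() -> AlertLibrary:
    """The packaged reactive-metabolite alert library.

    Contains the aromatic-amine (nitrogen-containing benzene) family — the
    any-substitution pattern and its two/one/no N-H variants — the other
    common reactive-metabolite motifs, and the decomposed ``nitrogen_compound``
    and ``benzene_ring`` patterns.
    """
    ref = resources.files("adalert.data").joinpath("builtin_alerts.csv")
    with resources.as_file(ref) as path:
        return load_alert_library(path, name="builtin")


def export_smarts(library: AlertLibrary, path: str | Path) -> None:
    """Write the library as a flat file: one ``alert_id<TAB>smarts`` per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for alert in library:
            handle.write(f"{alert.alert_id}\t{alert.smarts}\n")
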