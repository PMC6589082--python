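"""Named match statistics shared between patterns of a record.

A named pattern that matches binds a small dict of statistics (``length``,
``pattern_idx``, ``pattern_name``, ``edits``).  Later patterns — on the same
template line or on lines with a later processing order — can reference them
as ``%name.field%`` (pattern lengths, list selection, output file names).

Stores can be layered: a child store created with :meth:`VariableStore.child`
stages bindings for a tentative match attempt and only :meth:`commit`\\ s them
to its parent once the attempt succeeds, so a failed line or candidate never
leaks bindings.
"""

from __future__ import annotations

from typing import Any, Iterator, Mapping, Optional

from .errors import VariableError

FIELDS = ("length", "pattern_idx", "pattern_name", "edits")


def split_ref(ref: str) -> tuple[str, str]:
    """Split a ``name.field`` reference; a bare ``name`` defaults to ``length``."""
    name, dot, fld = ref.rpartition(".")
    if not dot:
        return ref, "length"
    return name, fld


class VariableStore:
    """Mapping from pattern name to its match statistics.

    A name binds at most once per record; rebinding raises
    :class:`VariableError`.
    """

    def __init__(self, parent: Optional["VariableStore"] = None):
        self._bindings: dict[str, dict[str, Any]] = {}
        self._parent = parent

    def child(self) -> "VariableStore":
        return VariableStore(parent=self)

    def is_bound(self, name: str) -> bool:
        if name in self._bindings:
            return True
        return self._parent.is_bound(name) if self._parent is not None else False

    def bind(self, name: str, stats: Mapping[str, Any]) -> None:
        if self.is_bound(name):
            raise VariableError(f"variable {name!r} is already bound")
        self._bindings[name] = dict(stats)

    def get(self, name: str) -> Mapping[str, Any]:
        if name in self._bindings:
            return self._bindings[name]
        if self._parent is not None:
            return self._parent.get(name)
        raise VariableError(
            f"unknown variable {name!r}; available: {sorted(self.names()) or 'none'}"
        )

    def lookup(self, ref: str) -> Any:
        name, fld = split_ref(ref)
        stats = self.get(name)
        if fld not in stats:
            raise VariableError(
                f"variable {name!r} has no field {fld!r}; "
                f"available fields: {sorted(stats)}"
            )
        return stats[fld]

    def names(self) -> set[str]:
        out = set(self._bindings)
        if self._parent is not None:
            out |= self._parent.names()
        return out

    def commit(self) -> None:
        """Push this layer's bindings into the parent store."""
        if self._parent is None:
            raise VariableError("cannot commit a root variable store")
        for name, stats in self._bindings.items():
            self._parent.bind(name, stats)
        self._bindings.clear()

    def items(self) -> Iterator[tuple[str, Mapping[str, Any]]]:
        seen = set()
        store: Optional[VariableStore] = self
        while store is not None:
            for name, stats in store._bindings.items():
                if name not in seen:
                    seen.add(name)
                    yield name, stats
            store = store._parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"VariableStore({dict(self.items())!r})"
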