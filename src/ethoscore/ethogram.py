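"""Ethogram definitions: behaviors, key/color bindings, session schemes.

An :class:`Ethogram` is the template for one behavioral test: an ordered
list of behaviors (``state`` behaviors are mutually exclusive and carry
duration; ``point`` behaviors are instantaneous counted events), each bound
to a single keyboard key and an RGB color, plus a session/trial scheme.

Built-in templates are provided for the forced swim test (FST), novel
object recognition (NOR) and the elevated plus maze (EPM).  Key bindings
and EPM colors are documented defaults (chosen here, not prescribed by any
external source); FST and NOR colors follow the conventional
blue/red/black/green palette.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import EthogramError, UnsupportedTemplateError

__all__ = [
    "Behavior",
    "SessionScheme",
    "Ethogram",
    "builtin_template",
    "customize_template",
    "BUILTIN_TEMPLATES",
]

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")

# sentinel: distinguishes "leave novel_designation alone" from "clear it"
_UNSET = object()


@dataclass(frozen=True)
class Behavior:
    """One scoreable behavioral element.

    Parameters
    ----------
    name : str
        Unique identifier within the ethogram.
    kind : {"state", "point"}
        ``state`` behaviors occupy time (bouts); ``point`` behaviors are
        instantaneous events.
    key : str
        Single printable character used to score this behavior.
    color : str
        6-hex-digit RGB string, e.g. ``"#0000FF"``.
    """

    name: str
    kind: str
    key: str
    color: str

    def __post_init__(self) -> None:
        if not self.name:
            raise EthogramError("behavior name must be non-empty")
        if self.kind not in ("state", "point"):
            raise EthogramError(
                f"behavior {self.name!r}: kind must be 'state' or 'point', got {self.kind!r}"
            )
        if len(self.key) != 1 or not self.key.isprintable():
            raise EthogramError(
                f"behavior {self.name!r}: key must be a single printable character, got {self.key!r}"
            )
        if not _HEX_COLOR.match(self.color):
            raise EthogramError(
                f"behavior {self.name!r}: color must be a 6-hex-digit RGB string, got {self.color!r}"
            )

    @property
    def rgb(self) -> tuple[int, int, int]:
        """Color as an (r, g, b) integer triple."""
        c = self.color.lstrip("#")
        return (int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16))


@dataclass(frozen=True)
class SessionScheme:
    """Number and duration of sessions/trials for a test."""

    n_sessions: int = 1
    trials_per_session: int = 1
    trial_duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or int(self.n_sessions) != self.n_sessions:
            raise EthogramError("n_sessions must be a positive integer")
        if self.trials_per_session < 1 or int(self.trials_per_session) != self.trials_per_session:
            raise EthogramError("trials_per_session must be a positive integer")
        if not self.trial_duration_s > 0:
            raise EthogramError("trial_duration_s must be > 0")


@dataclass(frozen=True)
class Ethogram:
    """A behavioral-test template.

    Invariants (checked on construction): at least one state behavior,
    behavior names and keys unique, ``novel_designation`` (if set) names a
    state behavior.
    """

    test_name: str
    behaviors: tuple[Behavior, ...]
    scheme: SessionScheme = field(default_factory=SessionScheme)
    novel_designation: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "behaviors", tuple(self.behaviors))
        self._validate()

    def _validate(self) -> None:
        if not self.test_name:
            raise EthogramError("test_name must be non-empty")
        names = [b.name for b in self.behaviors]
        keys = [b.key for b in self.behaviors]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise EthogramError(f"duplicate behavior name(s): {', '.join(dup)}")
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise EthogramError(f"duplicate key binding(s): {', '.join(dup)}")
        if not any(b.kind == "state" for b in self.behaviors):
            raise EthogramError("an ethogram needs at least one state behavior")
        if self.novel_designation is not None:
            b = self.find(self.novel_designation)
            if b is None:
                raise EthogramError(
                    f"novel_designation {self.novel_designation!r} names no behavior"
                )
            if b.kind != "state":
                raise EthogramError(
                    f"novel_designation {self.novel_designation!r} must name a state behavior"
                )

    # -- lookups ---------------------------------------------------------

    def find(self, name: str) -> Behavior | None:
        for b in self.behaviors:
            if b.name == name:
                return b
        return None

    def __getitem__(self, name: str) -> Behavior:
        b = self.find(name)
        if b is None:
            raise KeyError(name)
        return b

    @property
    def state_behaviors(self) -> tuple[Behavior, ...]:
        return tuple(b for b in self.behaviors if b.kind == "state")

    @property
    def point_behaviors(self) -> tuple[Behavior, ...]:
        return tuple(b for b in self.behaviors if b.kind == "point")

    @property
    def key_map(self) -> dict[str, Behavior]:
        return {b.key: b for b in self.behaviors}

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "scheme": {
                "n_sessions": self.scheme.n_sessions,
                "trials_per_session": self.scheme.trials_per_session,
                "trial_duration_s": self.scheme.trial_duration_s,
            },
            "novel_designation": self.novel_designation,
            "behaviors": [
                {"name": b.name, "kind": b.kind, "key": b.key, "color": b.color}
                for b in self.behaviors
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Ethogram":
        try:
            scheme = SessionScheme(**d.get("scheme", {}))
            behaviors = tuple(Behavior(**b) for b in d["behaviors"])
            return cls(
                test_name=d["test_name"],
                behaviors=behaviors,
                scheme=scheme,
                novel_designation=d.get("novel_designation"),
            )
        except (KeyError, TypeError) as exc:
            raise EthogramError(f"malformed ethogram definition: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Ethogram":
        d = yaml.safe_load(text)
        if not isinstance(d, Mapping):
            raise EthogramError("ethogram file does not contain a mapping")
        return cls.from_dict(d)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "Ethogram":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_yaml(fh.read())


# ---------------------------------------------------------------------------
# Built-in templates.  FST/NOR colors follow the conventional palette
# (immobility blue, swimming red, climbing black, head shake green; object A
# red, object B black, general area blue).  EPM colors and every key binding
# are package defaults.
# ---------------------------------------------------------------------------

def _fst() -> Ethogram:
    return Ethogram(
        test_name="FST",
        behaviors=(
            Behavior("immobility", "state", "i", "#0000FF"),
            Behavior("swimming", "state", "s", "#FF0000"),
            Behavior("climbing", "state", "c", "#000000"),
            Behavior("head_shake", "point", "h", "#00FF00"),
        ),
        scheme=SessionScheme(n_sessions=2, trials_per_session=1, trial_duration_s=300.0),
    )


def _nor() -> Ethogram:
    return Ethogram(
        test_name="NOR",
        behaviors=(
            Behavior("explore_A", "state", "a", "#FF0000"),
            Behavior("explore_B", "state", "b", "#000000"),
            Behavior("general_area", "state", "g", "#0000FF"),
        ),
        scheme=SessionScheme(n_sessions=1, trials_per_session=2, trial_duration_s=300.0),
        # default: object B is novel; override per trial for counterbalancing
        novel_designation="explore_B",
    )


def _epm() -> Ethogram:
    return Ethogram(
        test_name="EPM",
        behaviors=(
            Behavior("open_arm", "state", "o", "#FFA500"),
            Behavior("closed_arm", "state", "c", "#8B4513"),
            Behavior("center", "state", "n", "#808080"),
        ),
        scheme=SessionScheme(n_sessions=1, trials_per_session=1, trial_duration_s=300.0),
    )


BUILTIN_TEMPLATES: dict[str, callable] = {"FST": _fst, "NOR": _nor, "EPM": _epm}


def builtin_template(test_name: str) -> Ethogram:
    """Return a fully populated built-in :class:`Ethogram`.

    Parameters
    ----------
    test_name : {"FST", "NOR", "EPM"}

    Raises
    ------
    UnsupportedTemplateError
        If ``test_name`` is not one of the built-in templates.
    """
    try:
        factory = BUILTIN_TEMPLATES[test_name.upper()]
    except (KeyError, AttributeError):
        raise UnsupportedTemplateError(
            f"no built-in template {test_name!r}; available: {', '.join(BUILTIN_TEMPLATES)}"
        ) from None
    return factory()


def customize_template(
    base: Ethogram,
    *,
    rename_test: str | None = None,
    scheme: SessionScheme | None = None,
    remap: Mapping[str, str] | None = None,
    recolor: Mapping[str, str] | None = None,
    add: Iterable[Behavior] = (),
    remove: Iterable[str] = (),
    novel_designation: str | None | object = _UNSET,
) -> Ethogram:
    """Apply a set of edits to ``base`` and return a new validated ethogram.

    ``base`` is never modified.  ``remap``/``recolor`` map behavior name to
    the new key/color; ``remove`` lists behavior names to drop; ``add``
    appends new behaviors.  All ethogram invariants are re-checked on the
    result, so e.g. a key clash raises :class:`EthogramError`.
    """
    remap = dict(remap or {})
    recolor = dict(recolor or {})
    remove = set(remove)

    for name in list(remap) + list(recolor) + sorted(remove):
        if base.find(name) is None:
            raise EthogramError(f"edit references unknown behavior {name!r}")

    behaviors: list[Behavior] = []
    for b in base.behaviors:
        if b.name in remove:
            continue
        changes = {}
        if b.name in remap:
            changes["key"] = remap[b.name]
        if b.name in recolor:
            changes["color"] = recolor[b.name]
        behaviors.append(dataclasses.replace(b, **changes) if changes else b)
    behaviors.extend(add)

    new_novel = base.novel_designation if novel_designation is _UNSET else novel_designation
    if new_novel is not None and new_novel in remove:
        raise EthogramError(
            f"cannot remove behavior {new_novel!r}: it is the novel_designation"
        )
    if base.novel_designation in remove and novel_designation is _UNSET:
        raise EthogramError(
            f"cannot remove behavior {base.novel_designation!r}: it is the "
            "novel_designation (clear it in the same edit)"
        )

    return Ethogram(
        test_name=rename_test if rename_test is not None else base.test_name,
        behaviors=tuple(behaviors),
        scheme=scheme if scheme is not None else base.scheme,
        novel_designation=new_novel,
    )
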