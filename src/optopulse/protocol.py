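"""Line-delimited JSON control protocol.

Every command travels host -> device as one JSON object terminated by a
single line break, over any byte-stream transport (loopback, file, or a
real serial port).  Every request gets exactly one JSON-line reply with a
``status`` field (``ok`` or ``error``).

The wire schema is canonical to this package (the key names mirror
:class:`~optopulse.params.StimParams`); a firmware port could adopt it
unchanged.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any

from .device import DeviceBusyError, VirtualDevice
from .params import ParamError, StimParams

__all__ = [
    "Message",
    "MessageKind",
    "ProtocolError",
    "encode",
    "decode",
    "dispatch",
    "LineBuffer",
    "LoopbackTransport",
]


class ProtocolError(ValueError):
    """Malformed, unknown, or schema-violating message."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


class MessageKind(str, enum.Enum):
    PARAMS = "params"
    TRIGGER = "trigger"
    MOCK = "mock"
    PING = "ping"
    CALIBRATE = "calibrate"


@dataclass(frozen=True)
class Message:
    """One protocol message: a kind plus a JSON-serialisable payload.

    PARAMS     payload ``{"lasers": [<StimParams dict>, ...]}``
    TRIGGER    payload ``{}``
    MOCK       payload ``{"enabled": bool}``
    PING       payload ``{}`` (optionally ``{"echo": <any>}``)
    CALIBRATE  payload ``{"laser_id": int, "steps": [fractions...]}``
    """

    kind: MessageKind
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MessageKind(self.kind))


def _validate_payload(kind: MessageKind, payload: dict[str, Any]) -> None:
    if kind is MessageKind.PARAMS:
        lasers = payload.get("lasers")
        if not isinstance(lasers, list) or not lasers:
            raise ProtocolError("schema", "params payload needs a non-empty 'lasers' list")
        for entry in lasers:
            if not isinstance(entry, dict):
                raise ProtocolError("schema", "each lasers entry must be an object")
            try:
                StimParams.from_dict(entry)
            except ParamError as exc:
                raise ProtocolError("schema", f"laser entry invalid: {exc}") from exc
    elif kind is MessageKind.MOCK:
        if not isinstance(payload.get("enabled"), bool):
            raise ProtocolError("schema", "mock payload needs boolean 'enabled'")
    elif kind is MessageKind.CALIBRATE:
        steps = payload.get("steps")
        if "laser_id" not in payload:
            raise ProtocolError("schema", "calibrate payload needs 'laser_id'")
        if steps is not None:
            if not isinstance(steps, list) or not all(
                isinstance(s, (int, float)) and 0 < s <= 1 for s in steps
            ):
                raise ProtocolError("schema", "'steps' must be fractions in (0, 1]")


def encode(message: Message) -> str:
    """Serialize to one UTF-8 JSON line (stable key order, no NaN)."""
    obj = {"kind": message.kind.value, **message.payload}
    try:
        line = json.dumps(obj, sort_keys=True, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise ProtocolError("unserializable", str(exc)) from exc
    return line + "\n"


def decode(line: str) -> Message:
    """Parse one complete line back into a :class:`Message`.

    Raises :class:`ProtocolError` with ``reason`` in {``malformed-json``,
    ``unknown-kind``, ``schema``} and a field-level detail string.
    """
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise ProtocolError("malformed-json", str(exc)) from exc
    if not isinstance(obj, dict):
        raise ProtocolError("schema", "top level must be a JSON object")
    kind_raw = obj.pop("kind", None)
    if kind_raw is None:
        raise ProtocolError("schema", "missing 'kind'")
    try:
        kind = MessageKind(kind_raw)
    except ValueError as exc:
        raise ProtocolError("unknown-kind", str(kind_raw)) from exc
    _validate_payload(kind, obj)
    return Message(kind=kind, payload=obj)


def dispatch(device: VirtualDevice, message: Message, t_ms: float = 0.0) -> dict[str, Any]:
    """Route a decoded message to the device; always returns a reply object.

    Device-busy conditions surface as ``{"status": "error", ...}`` replies,
    never as exceptions.
    """
    kind = message.kind
    try:
        if kind is MessageKind.PING:
            return {"status": "ok", "kind": "ping", "echo": message.payload.get("echo")}
        if kind is MessageKind.PARAMS:
            plist = [StimParams.from_dict(d) for d in message.payload["lasers"]]
            ack = device.set_params(plist)
            return {"status": "ok", "kind": "params", "configured": ack["configured"]}
        if kind is MessageKind.TRIGGER:
            accepted = device.software_trigger(t_ms)
            return {"status": "ok" if accepted else "error", "kind": "trigger",
                    "accepted": accepted}
        if kind is MessageKind.MOCK:
            device.set_mock(message.payload["enabled"])
            return {"status": "ok", "kind": "mock", "enabled": device.mock}
        if kind is MessageKind.CALIBRATE:
            from . import calibration
            steps = message.payload.get("steps") or calibration.default_steps()
            return {"status": "ok", "kind": "calibrate",
                    "laser_id": message.payload["laser_id"],
                    "steps": list(steps), "pulse_s": calibration.CALIB_PULSE_S}
    except (DeviceBusyError, ParamError) as exc:
        return {"status": "error", "kind": kind.value, "error": str(exc)}
    raise AssertionError(f"unhandled kind {kind}")  # pragma: no cover


def encode_reply(reply: dict[str, Any]) -> str:
    """Replies use the same JSON-line framing as requests."""
    return json.dumps(reply, sort_keys=True, allow_nan=False) + "\n"


class LineBuffer:
    """Reassemble complete lines from an arbitrarily fragmented byte stream.

    Partial lines are buffered, never dropped; any fragmentation of the
    same byte stream yields the same line sequence.
    """

    def __init__(self) -> None:
        self._buf = b""

    def feed(self, data: bytes | str) -> list[str]:
        if isinstance(data, str):
            data = data.encode("utf-8")
        self._buf += data
        *complete, self._buf = self._buf.split(b"\n")
        return [c.decode("utf-8") for c in complete]

    @property
    def pending(self) -> bytes:
        return self._buf


class LoopbackTransport:
    """In-process transport: writes go straight to a virtual device.

    Mimics the serial link to the physical board: the host writes JSON
    lines, the device replies with JSON lines readable via
    :meth:`read_line`.  A clock callable provides the device time in ms.
    """

    def __init__(self, device: VirtualDevice, clock=None):
        self.device = device
        self.clock = clock or (lambda: 0.0)
        self._rx = LineBuffer()
        self._replies: list[str] = []

    def write_line(self, line: str) -> None:
        for complete in self._rx.feed(line):
            try:
                msg = decode(complete)
                reply = dispatch(self.device, msg, t_ms=self.clock())
            except ProtocolError as exc:
                reply = {"status": "error", "error": exc.reason, "detail": exc.detail}
            self._replies.append(encode_reply(reply))

    def read_line(self) -> str | None:
        return self._replies.pop(0) if self._replies else None
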