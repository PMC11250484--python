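"""Uniform chat-model contract: templates, sessions, scripted + live backends.

Every pipeline stage talks to the model through the same three pieces:

* :func:`render_prompt` fills a :class:`PromptTemplate`'s ``{{slot}}``
  markers and returns a :class:`RenderedPrompt` that remembers which
  template and slot values produced it;
* :func:`chat` appends a (user, model) turn pair to a
  :class:`ChatSession` — the full history is resent on every call, so
  step-2 prompts may omit the chunk text the session already carries;
* a backend answers prompts. The :class:`ScriptedBackend` is a lookup
  table keyed by (template id, canonicalized key-slot values, chunk id):
  bitwise deterministic, offline, and the basis of the whole test suite.
  The :class:`LiveBackend` speaks the chat-completion HTTP contract and
  is never required by tests.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from ._text import normalize_ws

__all__ = [
    "PromptTemplate",
    "RenderedPrompt",
    "ChatTurn",
    "ChatSession",
    "GenerationSettings",
    "BackendScript",
    "ScriptedBackend",
    "LiveBackend",
    "TranscriptLog",
    "render_prompt",
    "chat",
    "load_template",
]

logger = logging.getLogger(__name__)

TASKS = (
    "schema_design",
    "ner_step1",
    "ner_step2",
    "re_step1",
    "re_step2",
    "vanilla_ner",
    "vanilla_re",
    "disambiguation",
    "triple_classification",
    "relation_prediction",
    "link_prediction_tail",
    "link_prediction_head",
)

_SLOT = re.compile(r"\{\{\s*([A-Za-z0-9_]+)\s*\}\}")


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt body with named ``{{slot}}`` markers.

    ``key_slots`` names the subset of slots that identify a scripted
    response; by default every slot is a key slot. Long free-text slots
    (the chunk text, serialized triples) are excluded from keys by the
    built-in templates so that scripted lookups stay reproducible.
    """

    id: str
    task: str
    body: str
    slots: tuple[str, ...]
    key_slots: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown template task {self.task!r}")
        referenced = set(_SLOT.findall(self.body))
        undeclared = referenced - set(self.slots)
        if undeclared:
            raise ValueError(
                f"template {self.id!r} references undeclared slots: {sorted(undeclared)}"
            )

    def effective_key_slots(self) -> tuple[str, ...]:
        return self.slots if self.key_slots is None else self.key_slots


@dataclass(frozen=True)
class RenderedPrompt:
    text: str
    template_id: str
    task: str
    slots: tuple[tuple[str, str], ...]
    key_extra: tuple[tuple[str, str], ...] = ()

    def script_key(self, key_slots: tuple[str, ...] | None = None):
        slot_map = dict(self.slots)
        keys = slot_map if key_slots is None else {
            k: slot_map[k] for k in key_slots if k in slot_map
        }
        return _canonical_key(self.template_id, {**keys, **dict(self.key_extra)})


def _canonical_key(template_id: str, slots: dict) -> tuple:
    return (
        template_id,
        tuple(sorted((k, normalize_ws(str(v))) for k, v in slots.items())),
    )


def render_prompt(
    template: PromptTemplate,
    slots: dict,
    *,
    key_extra: dict | None = None,
    strict: bool = True,
) -> RenderedPrompt:
    """Fill the template; every slot value appears verbatim in the output.

    Missing declared slots raise, naming the slot. Extra undeclared slot
    values raise in strict mode (the default) and are ignored otherwise.
    """
    missing = [s for s in template.slots if s not in slots]
    if missing:
        raise KeyError(f"template {template.id!r}: missing slot(s) {missing}")
    extra = [s for s in slots if s not in template.slots]
    if extra and strict:
        raise KeyError(f"template {template.id!r}: undeclared slot value(s) {extra}")

    text = _SLOT.sub(lambda m: str(slots[m.group(1)]), template.body)
    if _SLOT.search(text):
        raise ValueError(f"template {template.id!r}: unresolved slot markers remain")
    kept = tuple((k, str(v)) for k, v in slots.items() if k in template.slots)
    # key slots are resolved at render time so the prompt is self-describing
    key_slot_names = template.effective_key_slots()
    key_items = tuple((k, v) for k, v in kept if k in key_slot_names)
    return RenderedPrompt(
        text=text,
        template_id=template.id,
        task=template.task,
        slots=key_items if template.key_slots is not None else kept,
        key_extra=tuple(sorted((key_extra or {}).items())),
    )


# ---------------------------------------------------------------------------
# sessions

@dataclass(frozen=True)
class ChatTurn:
    role: str  # "user" | "model"
    content: str


@dataclass
class ChatSession:
    id: str
    turns: list[ChatTurn] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def check_alternation(self) -> bool:
        """Roles must alternate user, model, user, model, ..."""
        return all(
            t.role == ("user" if i % 2 == 0 else "model")
            for i, t in enumerate(self.turns)
        )

    def copy(self) -> "ChatSession":
        return ChatSession(id=self.id, turns=list(self.turns), meta=dict(self.meta))


@dataclass(frozen=True)
class GenerationSettings:
    temperature: float = 0.0
    max_output_tokens: int = 1024
    retries: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.retries < 0:
            raise ValueError("retries must be >= 0")


class TranscriptLog:
    """Append-only JSONL record of every prompt/response exchange."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.records: list[dict] = []

    def append(self, record: dict) -> None:
        self.records.append(record)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# backends

class Backend(Protocol):
    def respond(self, prompt: RenderedPrompt | str, session: ChatSession) -> str: ...


@dataclass
class BackendScript:
    """Deterministic response table for offline runs.

    Entries map (template id, canonicalized key-slot values, optional
    chunk id) to a response; lookups are total via ``default_response``.
    """

    entries: dict = field(default_factory=dict)
    default_response: str = "unknown"

    def add(self, template_id: str, slots: dict, response: str, chunk_id: str = "") -> None:
        key_slots = dict(slots)
        if chunk_id:
            key_slots["chunk_id"] = chunk_id
        self.entries[_canonical_key(template_id, key_slots)] = response

    def lookup(self, key: tuple) -> str | None:
        return self.entries.get(key)

    def to_dict(self) -> dict:
        return {
            "default_response": self.default_response,
            "entries": [
                {"template": tid, "slots": dict(slots), "response": resp}
                for (tid, slots), resp in sorted(self.entries.items())
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BackendScript":
        script = cls(default_response=data.get("default_response", "unknown"))
        for e in data.get("entries", []):
            script.entries[_canonical_key(e["template"], e.get("slots", {}))] = e["response"]
        return script

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "BackendScript":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


class ScriptedBackend:
    """Replays a :class:`BackendScript`; counts calls and missed lookups."""

    def __init__(self, script: BackendScript):
        self.script = script
        self.n_calls = 0
        self.calls_by_task: dict[str, int] = {}
        self.misses: list[tuple] = []

    def respond(self, prompt: RenderedPrompt | str, session: ChatSession) -> str:
        self.n_calls += 1
        if not isinstance(prompt, RenderedPrompt):
            return self.script.default_response
        self.calls_by_task[prompt.task] = self.calls_by_task.get(prompt.task, 0) + 1
        key = prompt.script_key()
        response = self.script.lookup(key)
        if response is None:
            self.misses.append(key)
            logger.warning("scripted backend miss for %s; using default", key[0])
            return self.script.default_response
        return response


class LiveBackend:
    """Minimal chat-completion HTTP client (OpenAI-style JSON contract).

    Resends the full session history on every call so step-2 prompts are
    conditioned on their step-1 exchange regardless of server-side state.
    Exists for real deployments; no test exercises it.
    """

    def __init__(
        self,
        url: str,
        model: str,
        api_key: str = "",
        settings: GenerationSettings = GenerationSettings(),
        timeout: float = 120.0,
    ):
        self.url = url
        self.model = model
        self.api_key = api_key
        self.settings = settings
        self.timeout = timeout
        self.n_calls = 0

    def respond(self, prompt: RenderedPrompt | str, session: ChatSession) -> str:
        self.n_calls += 1
        messages = [
            {"role": "assistant" if t.role == "model" else "user", "content": t.content}
            for t in session.turns
        ]
        payload = {
            "model": self.model,
            "messages": messages,
            "temperature": self.settings.temperature,
            "max_tokens": self.settings.max_output_tokens,
        }
        if self.settings.seed is not None:
            payload["seed"] = self.settings.seed
        body = json.dumps(payload).encode("utf-8")
        headers = {"Content-Type": "application/json"}
        if self.api_key:
            headers["Authorization"] = f"Bearer {self.api_key}"
        last_err: Exception | None = None
        for _ in range(self.settings.retries + 1):
            try:
                req = urllib.request.Request(self.url, data=body, headers=headers)
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    data = json.loads(resp.read().decode("utf-8"))
                return data["choices"][0]["message"]["content"]
            except Exception as err:  # noqa: BLE001 - transport errors retried
                last_err = err
        raise TransportError(f"backend call failed after retries: {last_err}", session)


class TransportError(RuntimeError):
    """Raised when a live backend is unreachable; carries the session."""

    def __init__(self, message: str, session: ChatSession):
        super().__init__(message)
        self.session = session


# ---------------------------------------------------------------------------

def chat(
    session: ChatSession,
    prompt: RenderedPrompt | str,
    backend: Backend,
    settings: GenerationSettings = GenerationSettings(),
    log: TranscriptLog | None = None,
) -> tuple[str, ChatSession]:
    """One exchange: append the user turn, obtain and append the model turn."""
    text = prompt.text if isinstance(prompt, RenderedPrompt) else str(prompt)
    if not text.strip():
        raise ValueError("prompt text is empty")
    session.turns.append(ChatTurn("user", text))
    response = backend.respond(prompt, session)
    session.turns.append(ChatTurn("model", response if response.strip() else "(empty)"))
    if log is not None:
        log.append(
            {
                "session": session.id,
                "template": getattr(prompt, "template_id", ""),
                "prompt": text,
                "response": response,
                "meta": dict(session.meta),
            }
        )
    return response, session


# ---------------------------------------------------------------------------
# template files: YAML header between '---' fences, then the body

def load_template(path: str | Path) -> PromptTemplate:
    raw = Path(path).read_text(encoding="utf-8")
    m = re.match(r"\s*---\s*\n(.*?)\n---\s*\n(.*)\Z", raw, re.S)
    if not m:
        raise ValueError(f"{path}: expected a '---' fenced YAML header")
    import yaml

    header = yaml.safe_load(m.group(1)) or {}
    return PromptTemplate(
        id=header["id"],
        task=header.get("task", header["id"]),
        body=m.group(2).strip("\n"),
        slots=tuple(header.get("slots", [])),
        key_slots=tuple(header["key_slots"]) if "key_slots" in header else None,
    )


def load_template_dir(path: str | Path) -> dict[str, PromptTemplate]:
    templates = {}
    for p in sorted(Path(path).glob("*.tmpl")):
        t = load_template(p)
        templates[t.id] = t
    return templates
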