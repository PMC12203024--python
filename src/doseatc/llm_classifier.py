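"""Prompted LLM classification of daily-dose strings into ATC level-2 codes.

Two prompt versions are bundled: ``initial`` (few-shot, concise two-field
output) and ``revised`` (chain-of-thought: the model reasons step by step
about the total daily dose before emitting its codes).  The revised prompt
asks for a pipe-delimited completion::

    <Reasoning>|<Most likely level 2 ATC Code>|<Next most likely (or "NA")>

Completions are parsed by taking the *last two* pipe-separated tokens as the
candidate codes and everything before them as reasoning — the reasoning is
unconstrained free text that may itself contain pipes and newlines.  Any
failure to produce two valid trailing fields is recorded as a delimiter
error, never raised: parsing is total.

The transport is a pluggable :class:`CompletionBackend`.  A deterministic,
rule-based mock lives in :mod:`doseatc.synthetic_data`; a thin OpenAI-style
live backend is provided for real use but is configuration-gated and never
touched by the test suite.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Protocol

from .atc_codes import parse_level2
from .errors import (
    ConfigurationError,
    DuplicateInputError,
    InvalidCodeError,
    UnknownPromptVersionError,
)

#: Completion settings used throughout: temperature 0 for maximal determinism,
#: a 1000-token cap (long enough for step-by-step reasoning, short enough to
#: cut off runaway explanations).
DEFAULT_TEMPERATURE = 0.0
DEFAULT_MAX_TOKENS = 1000
DEFAULT_MODEL_ID = "gpt-4o-2024-05-13"

PROMPT_VERSIONS = ("initial", "revised")

STATUS_OK = "ok"
STATUS_NA = "na"
STATUS_DELIMITER_ERROR = "delimiter_error"
STATUS_FAILED = "failed"

NA_TOKEN = "NA"


@dataclass(frozen=True)
class PromptVersion:
    name: str
    system_text: str


@dataclass(frozen=True)
class ClassificationRequest:
    request_id: str
    system_text: str
    user_text: str
    temperature: float = DEFAULT_TEMPERATURE
    max_tokens: int = DEFAULT_MAX_TOKENS
    model_id: str = DEFAULT_MODEL_ID


@dataclass(frozen=True)
class CompletionResult:
    """One raw completion (or a permanent failure) for a request."""

    request_id: str
    user_text: str
    text: str | None
    status: str  # "ok" or "failed"
    error: str | None = None


@dataclass(frozen=True)
class ParsedClassification:
    """Structured view of one completion.

    ``status`` partitions outcomes exhaustively: ``ok`` (best code valid),
    ``na`` (the model declined: best field was "NA"), or ``delimiter_error``
    (the completion could not be split into reasoning plus two code fields;
    the full raw text is preserved in ``raw``).
    """

    reasoning: str
    best: str | None
    next_best: str | None
    status: str
    raw: str = ""


class CompletionBackend(Protocol):
    """Contract a completion transport must satisfy."""

    def complete(
        self,
        system_text: str,
        user_text: str,
        temperature: float,
        max_tokens: int,
        model_id: str,
    ) -> str: ...


class TransientBackendError(Exception):
    """A retryable transport failure (rate limit, timeout, 5xx)."""


class PermanentBackendError(Exception):
    """A non-retryable failure; the item is recorded as failed."""


def build_prompt(version: str) -> PromptVersion:
    """Load a bundled prompt version (``initial`` or ``revised``) verbatim."""
    if version not in PROMPT_VERSIONS:
        raise UnknownPromptVersionError(
            f"unknown prompt version {version!r}; expected one of {PROMPT_VERSIONS}"
        )
    text = (
        resources.files("doseatc.data.prompts").joinpath(f"{version}.txt").read_text("utf-8")
    )
    return PromptVersion(name=version, system_text=text)


def build_batch(
    dose_strings: Iterable[str],
    prompt: PromptVersion | str = "revised",
    temperature: float = DEFAULT_TEMPERATURE,
    max_tokens: int = DEFAULT_MAX_TOKENS,
    model_id: str = DEFAULT_MODEL_ID,
) -> list[ClassificationRequest]:
    """One request per distinct dose string, ids derived from the index.

    Duplicate inputs are rejected: the dose-string construction already
    dedupes, so a duplicate here means the caller skipped that step.
    """
    if isinstance(prompt, str):
        prompt = build_prompt(prompt)
    strings = list(dose_strings)
    duplicates = {s for s in strings if strings.count(s) > 1}
    if duplicates:
        raise DuplicateInputError(f"duplicate dose strings in batch: {sorted(duplicates)!r}")
    return [
        ClassificationRequest(
            request_id=f"req-{index:06d}",
            system_text=prompt.system_text,
            user_text=text,
            temperature=temperature,
            max_tokens=max_tokens,
            model_id=model_id,
        )
        for index, text in enumerate(strings)
    ]


def classify_batch(
    requests: list[ClassificationRequest],
    backend: CompletionBackend,
    max_attempts: int = 3,
    backoff_seconds: float = 1.0,
    sleep: Callable[[float], None] = time.sleep,
) -> list[CompletionResult]:
    """Run a batch against a backend; a batch always completes.

    Transient transport errors are retried up to ``max_attempts`` times with
    exponential backoff; an item that keeps failing (or fails permanently) is
    recorded with status ``failed`` rather than aborting the remaining items.
    Results are order-aligned with the requests.
    """
    results: list[CompletionResult] = []
    for request in requests:
        text: str | None = None
        error: str | None = None
        for attempt in range(max_attempts):
            try:
                text = backend.complete(
                    request.system_text,
                    request.user_text,
                    request.temperature,
                    request.max_tokens,
                    request.model_id,
                )
                error = None
                break
            except TransientBackendError as exc:
                error = str(exc)
                if attempt < max_attempts - 1:
                    sleep(backoff_seconds * 2**attempt)
            except PermanentBackendError as exc:
                error = str(exc)
                break
        results.append(
            CompletionResult(
                request_id=request.request_id,
                user_text=request.user_text,
                text=text,
                status=STATUS_OK if text is not None else STATUS_FAILED,
                error=error,
            )
        )
    return results


def _parse_code_field(token: str) -> tuple[str | None, bool]:
    """Return (code-or-None, ok).  "NA" (any case) maps to None."""
    stripped = token.strip()
    if not stripped:
        return None, False
    if stripped.upper() == NA_TOKEN:
        return None, True
    try:
        return parse_level2(stripped), True
    except InvalidCodeError:
        return None, False


def parse_completion(raw: str) -> ParsedClassification:
    """Parse a completion into reasoning plus best/next-best level-2 codes.

    The last two pipe-separated tokens are the candidate code fields;
    everything before them is reasoning (which may contain pipes, newlines and
    trailing prose — chain-of-thought output is unconstrained).  "NA" in a
    code field means "no code".  Anything that prevents recovering two valid
    trailing fields — no pipe at all, an empty final field, a token that is
    neither "NA" nor a valid code — yields status ``delimiter_error`` with the
    raw text preserved.  This function never raises.
    """
    tokens = raw.split("|")
    if len(tokens) < 2:
        return ParsedClassification("", None, None, STATUS_DELIMITER_ERROR, raw=raw)
    best_token, next_token = tokens[-2], tokens[-1]
    reasoning = "|".join(tokens[:-2]).strip()
    best, best_ok = _parse_code_field(best_token)
    next_best, next_ok = _parse_code_field(next_token)
    if not (best_ok and next_ok):
        return ParsedClassification("", None, None, STATUS_DELIMITER_ERROR, raw=raw)
    status = STATUS_OK if best is not None else STATUS_NA
    return ParsedClassification(reasoning, best, next_best, status, raw=raw)


class LiveOpenAIBackend:
    """Minimal chat-completions client over the OpenAI HTTP API.

    Requires an API key (``api_key`` argument or ``OPENAI_API_KEY`` in the
    environment); construction fails fast with :class:`ConfigurationError`
    before any network call when credentials are absent.  Exists for real
    deployments; all offline work uses the mock backend in
    :mod:`doseatc.synthetic_data`.
    """

    def __init__(self, api_key: str | None = None, base_url: str = "https://api.openai.com/v1"):
        import os

        self.api_key = api_key or os.environ.get("OPENAI_API_KEY")
        if not self.api_key:
            raise ConfigurationError(
                "live backend requires an API key (OPENAI_API_KEY or api_key=...)"
            )
        self.base_url = base_url.rstrip("/")

    def complete(self, system_text, user_text, temperature, max_tokens, model_id):
        import urllib.request

        payload = json.dumps(
            {
                "model": model_id,
                "temperature": temperature,
                "max_tokens": max_tokens,
                "messages": [
                    {"role": "system", "content": system_text},
                    {"role": "user", "content": user_text},
                ],
            }
        ).encode("utf-8")
        request = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=120) as response:
                body = json.loads(response.read().decode("utf-8"))
        except Exception as exc:  # transport-level: let the batch runner retry
            raise TransientBackendError(str(exc)) from exc
        return body["choices"][0]["message"]["content"]


def write_requests_jsonl(requests: list[ClassificationRequest], path: str | Path) -> None:
    """One request object per line: request_id, system, user, temperature,
    max_tokens, model.  Vendor-neutral; adapt as needed for a batch API."""
    with open(path, "w", encoding="utf-8") as handle:
        for r in requests:
            handle.write(
                json.dumps(
                    {
                        "request_id": r.request_id,
                        "system": r.system_text,
                        "user": r.user_text,
                        "temperature": r.temperature,
                        "max_tokens": r.max_tokens,
                        "model": r.model_id,
                    }
                )
                + "\n"
            )


def write_results_jsonl(results: list[CompletionResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for r in results:
            handle.write(
                json.dumps(
                    {"request_id": r.request_id, "input": r.user_text, "text": r.text, "status": r.status}
                )
                + "\n"
            )


def read_results_jsonl(path: str | Path) -> list[CompletionResult]:
    results = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        results.append(
            CompletionResult(
                request_id=obj["request_id"],
                user_text=obj.get("input", ""),
                text=obj.get("text"),
                status=obj.get("status", STATUS_OK),
            )
        )
    return results
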