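"""Score renderings: score_ascii, score_html and sp_ascii.

score_ascii replaces every residue by its 0-9 scaled residue score, with a
header carrying the whole-alignment SCORE (0-1000) and one 0-100 display
value per sequence, and a ``cons`` line of scaled column scores under each
block.  score_html is the same information as a standalone colourised page
(10 bins from blue at 0 to dark pink at 9, no external assets).  sp_ascii
lists every aligned residue pair with its pair score; it is only available
when pair scores were retained.
"""

from __future__ import annotations

from .alignment import GAP, Alignment
from .errors import PairScoresUnavailableError
from .tcs import TcsScores, scale_to_0_9

BLOCK_WIDTH = 60

# 10-bin ramp, blue (score 0) to dark pink (score >= 9); artifact constants.
_RAMP_ENDPOINTS = ((0, 0, 179), (199, 21, 133))


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def display_score(alignment_tcs: float) -> int:
    """AlignmentTCS normalised to a maximum of 1000."""
    return _round_half_away(alignment_tcs * 1000.0)


def sequence_display(sequence_tcs: float) -> int:
    """SequenceTCS normalised to a maximum of 100."""
    return _round_half_away(sequence_tcs * 100.0)


def _digit_rows(aln: Alignment, scores: TcsScores) -> list[str]:
    rows = []
    for s, row in enumerate(aln.rows):
        out, pos = [], 0
        for ch in row:
            if ch == GAP:
                out.append(GAP)
            else:
                pos += 1
                out.append(str(scale_to_0_9(scores.residue_scores[(s, pos)])))
        rows.append("".join(out))
    return rows


def _cons_digits(scores: TcsScores) -> str:
    return "".join(str(d) for d in scores.scaled_column_scores())


def render_score_ascii(aln: Alignment, scores: TcsScores) -> str:
    """Plain-text score report; the digit grid is exactly N x L."""
    digits = _digit_rows(aln, scores)
    cons = _cons_digits(scores)
    pad = max(len(n) for n in aln.names + ["cons"]) + 2
    lines = [
        "TCS evaluation (tcscore)",
        f"SCORE={display_score(scores.alignment_score)}",
        "*",
        " BAD AVG GOOD",
        "*",
    ]
    for name, sval in zip(aln.names, scores.sequence_scores):
        lines.append(f"{name:<{pad}}: {sequence_display(float(sval)):>3}")
    lines.append("")
    for start in range(0, aln.length, BLOCK_WIDTH):
        end = min(start + BLOCK_WIDTH, aln.length)
        for name, drow in zip(aln.names, digits):
            lines.append(f"{name:<{pad}}{drow[start:end]}")
        lines.append(f"{'cons':<{pad}}{cons[start:end]}")
        lines.append("")
    return "\n".join(lines)


def parse_score_ascii(text: str) -> dict:
    """Parse a score_ascii report back into its numeric content.

    Returns ``score`` (int 0-1000), ``sequence_displays`` (name -> int),
    ``digits`` (name -> full digit/gap row) and ``cons`` (column digits).
    """
    lines = text.splitlines()
    score = None
    seq_displays: dict[str, int] = {}
    digits: dict[str, str] = {}
    cons = ""
    in_blocks = False
    for ln in lines:
        if ln.startswith("SCORE="):
            score = int(ln.split("=", 1)[1])
            continue
        if not ln.strip() or ln.strip() == "*" or "BAD AVG GOOD" in ln \
                or ln.startswith("TCS evaluation"):
            continue
        if ":" in ln and not in_blocks:
            name, val = ln.split(":", 1)
            seq_displays[name.strip()] = int(val)
            continue
        in_blocks = True
        name, chunk = ln.split(None, 1)
        if name == "cons":
            cons += chunk.strip()
        else:
            digits[name] = digits.get(name, "") + chunk.strip()
    return {"score": score, "sequence_displays": seq_displays,
            "digits": digits, "cons": cons}


def _color_ramp() -> list[str]:
    (r0, g0, b0), (r1, g1, b1) = _RAMP_ENDPOINTS
    out = []
    for k in range(10):
        t = k / 9.0
        out.append("#{:02x}{:02x}{:02x}".format(
            round(r0 + (r1 - r0) * t), round(g0 + (g1 - g0) * t),
            round(b0 + (b1 - b0) * t)))
    return out


def render_score_html(aln: Alignment, scores: TcsScores) -> str:
    """Standalone HTML page colourising residues by scaled score."""
    ramp = _color_ramp()
    css = "\n".join(
        f".t{k} {{ background: {c}; color: #ffffff; }}"
        for k, c in enumerate(ramp))
    digits = _digit_rows(aln, scores)
    pad = max(len(n) for n in aln.names + ["cons"]) + 2
    body: list[str] = []
    body.append(f"<p class='score'>SCORE={display_score(scores.alignment_score)}</p>")
    body.append("<ul class='seqs'>")
    for name, sval in zip(aln.names, scores.sequence_scores):
        body.append(f"<li>{name} : {sequence_display(float(sval))}</li>")
    body.append("</ul>")
    body.append("<pre>")
    cons = _cons_digits(scores)
    for start in range(0, aln.length, BLOCK_WIDTH):
        end = min(start + BLOCK_WIDTH, aln.length)
        for name, row, drow in zip(aln.names, aln.rows, digits):
            cells = []
            for ch, d in zip(row[start:end], drow[start:end]):
                if ch == GAP:
                    cells.append(GAP)
                else:
                    cells.append(f"<span class=\"t{d}\">{ch}</span>")
            body.append(f"{name:<{pad}}" + "".join(cells))
        body.append(f"{'cons':<{pad}}{cons[start:end]}")
        body.append("")
    body.append("</pre>")
    return (
        "<!DOCTYPE html>\n<html>\n<head>\n<meta charset=\"utf-8\"/>\n"
        "<title>TCS evaluation</title>\n<style>\n"
        "body { font-family: monospace; }\n" + css + "\n</style>\n</head>\n"
        "<body>\n" + "\n".join(body) + "\n</body>\n</html>\n")


def render_sp_ascii(aln: Alignment, scores: TcsScores) -> str:
    """Pair-level report: one record per aligned residue pair.

    Raises :class:`PairScoresUnavailableError` when pair scores were
    discarded at scoring time (memory-saving mode).
    """
    if scores.pair_scores is None:
        raise PairScoresUnavailableError(
            "pair scores were not retained; rerun scoring with keep_pairs=True")
    lines = ["# seq_x seq_y pos_x pos_y column pair_tcs"]
    for ((x, i), (y, j)), s in sorted(
            scores.pair_scores.items(),
            key=lambda kv: (scores.pair_columns[kv[0]], kv[0])):
        col = scores.pair_columns[((x, i), (y, j))]
        lines.append(f"{aln.names[x]} {aln.names[y]} {i} {j} {col} {s:.4f}")
    return "\n".join(lines) + "\n"
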