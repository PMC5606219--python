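"""Self-contained sessions: save, reload without inputs, export reports.

Maps a small dataset, applies a filter, saves the session, then reloads it
and regenerates the same filter result, the text summary and the SVG panel
figure purely from the session file.
"""

import tempfile
from pathlib import Path

from genecontext import Settings, TrackKey, build_panels
from genecontext.pattern_search import FilterChain, GeneSizeFilter, apply_chain
from genecontext.session_io import (
    SessionState,
    export_summary,
    export_svg,
    load_session,
    save_session,
)
from genecontext.synthetic import make_annotation, make_background_peaks

ann = make_annotation(n_genes=12, seed=8)
key = TrackKey("ESC", "H3K27me3")
panels = build_panels(
    ann.genes, [make_background_peaks(ann, key, 5.0, seed=9)], [],
    Settings(flank_up=10_000, flank_down=10_000), ann)
chain = FilterChain([GeneSizeFilter(">", 8_000)])
apply_chain(chain, panels)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session.json"
    state = SessionState(settings=Settings(10_000, 10_000), panels=panels,
                         filter_chain=chain, genome_label="demo")
    save_session(state, path)
    print(f"session: {path.stat().st_size} bytes of canonical JSON")

    # reload — no annotation or peak files needed from here on
    reloaded = load_session(path)
    survivors, trace = apply_chain(reloaded.filter_chain, reloaded.panels)
    print(f"reloaded {len(reloaded.panels)} panels; "
          f"{trace[-1]} genes pass the size filter")

    summary = export_summary(reloaded)
    print("\n".join(summary.splitlines()[:3]))

    svg = export_svg([p for p in reloaded.panels if p.show],
                     reloaded.settings, Path(tmp) / "panels.svg")
    print(f"SVG figure: {len(svg)} characters, "
          f"{svg.count('gene-panel')} gene panel groups")
# The summary lists every filter with its survivor count and ends with the
# machine-parseable gene list; the SVG shows each shown gene with its scale
# line, gene bar, peaks (opacity ~ score) and expression swatch.
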