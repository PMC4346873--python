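"""The end-to-end pipeline: screen -> targets -> networks -> report.

Writes a YAML config pointing at the packaged fixtures, runs every stage and
prints the machine-readable summary. All artifacts (active compound table,
gated interactions, four network exports, markdown report, run manifest)
land in a temporary output directory.
"""

import json
import tempfile
from pathlib import Path

from herbnet.pipeline import load_config, run_pipeline
from herbnet.synthetic import fixture_path

workdir = Path(tempfile.mkdtemp(prefix="herbnet-"))
config_file = workdir / "pipeline.yml"
config_file.write_text(
    f"""\
compounds: {fixture_path('table1')}
targets: {fixture_path('table2')}
interactions: {fixture_path('it_edges')}
pathways: {fixture_path('pathways')}
diseases: {fixture_path('diseases')}
metabolite_map: {fixture_path('metabolite_map')}
dt_edges: {fixture_path('dt_edges')}
disease_terms: [inflammation]
rescues:
  - kind: content_rescue
    content_min: 7.0
  - kind: metabolite_rescue
"""
)

summary = run_pipeline(load_config(config_file), workdir / "out")
print(json.dumps(summary, indent=2, sort_keys=True))
print(f"\nartifacts in {workdir / 'out'}:")
for artifact in sorted((workdir / "out").iterdir()):
    print(f"  {artifact.name}")
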