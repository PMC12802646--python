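# Packaged fixtures (all synthetic)

Every file in this directory is a synthetic stand-in constructed for tests
and examples; none reproduces a published gene list.

- `synthetic_sngs/sng[1-9].synthetic.gmt` — nine senescence gene sets with
  uneven sizes and a heavy singleton tail in their union, mimicking the
  statistical shape of the published senescence-gene-set literature. Two sets
  (`sng3`, `sng7`) carry per-gene direction annotations as TSV sidecars.
- `synthetic_sngs/core_panel.synthetic.tsv` — the 39-gene consensus panel
  (genes present in at least five of the nine sets), with direction labels.
  It contains canonical senescence markers (CDKN1A, CDKN2A, ...) plus
  synthetic filler symbols in the surrounding sets.
- `mock_xenium_base_panel.synthetic.tsv` — a 377-symbol mock "multi-tissue"
  base panel sized like a commercial in-situ panel, using the synthetic
  generator's background-gene namespace.
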