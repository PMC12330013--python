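# Catalog configuration schema

`sqmine scan --catalog catalog.yml` (or `sqmine.load_catalog(path)`)
merges a YAML document over the built-in defaults: entries with the same
key replace the default entry, everything else is kept. Pass
`merge_defaults=False` in the API for a config-only catalog.

```yaml
families:
  # partial override: only the cutoff changes, the default description stays
  SftT:
    bitscore_cutoff: 150
  # new family
  MyFam:
    description: my enzyme
    bitscore_cutoff: 100        # optional, default 100 (bits, inclusive)

pathways:
  # replaces the default sulfo-SFT definition entirely
  sulfo-SFT:
    arrangements:               # >= 1 ordered family-id list
      - [SftA, SftI, YihQ, SftR, SftT]
      - [SftI, SftR, SftT]
    core: [SftI, SftR, SftT]    # required within ONE matched block
    accessory: [SftA, YihQ]     # optional members (documentation + flags)
```

Validation rules (violations raise `CatalogError` naming the entry):

- every family referenced by a pathway (arrangements, core, accessory)
  must exist in `families`;
- arrangements are non-empty; each arrangement contains at least one core
  family; the core set is covered by the union of arrangement families;
- `bitscore_cutoff` > 0; unknown keys are rejected.

`Catalog.to_yaml()` serializes any catalog back into this format;
loading the result reproduces the catalog exactly.
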