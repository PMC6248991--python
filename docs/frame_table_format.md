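# Plain frame-table trajectory format

A hand-writable text container for small fixtures and generated ensembles,
read and written by `memdyn.io_model`. Units: Å for coordinates and box
lengths, ps for times.

```
# natoms N
# frame <time_ps> [<Lx> <Ly> <Lz>]
x y z          (N rows, whitespace-separated floats)
# frame <time_ps> [<Lx> <Ly> <Lz>]
x y z
...
```

Rules:

* The first line must be exactly `# natoms N`.
* Each frame starts with a `# frame` header carrying the frame time and,
  optionally, the orthorhombic box lengths. Box metadata must be present
  either on every frame or on none.
* Exactly `N` coordinate rows follow each header; a short final block is a
  truncation error that names the frame index.
* The writer emits times/boxes with `%.8g` and coordinates with `%.8f`;
  a write→read round trip reproduces coordinates bit-for-bit at that stored
  precision.
* Frame times must be strictly increasing.

DCD and XTC are also supported (via MDAnalysis) for interoperability with
standard MD tooling; their round-trip precision is limited by the container
(single-precision for DCD, 0.001-nm lattice for XTC). Non-orthorhombic
boxes are rejected on read.
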