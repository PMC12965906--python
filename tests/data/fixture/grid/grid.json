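{
 "format_version": 1,
 "kind": "climate_grid",
 "x0": -120.0,
 "y0": 50.0,
 "dx": 0.3,
 "dy": 0.3,
 "crs": "EPSG:4326",
 "nodata": -9999.0,
 "bands": [
  "TD",
  "MWMT",
  "MAP",
  "MAT"
 ],
 "mask": false
}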