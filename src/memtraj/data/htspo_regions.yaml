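# Default residue regions for the 169-residue human translocator protein (UniProt P30536).
#
# TM helix boundaries are not part of the UniProt record used here; they are inferred
# from the loop definitions (LP I = V26-H46, etc.) and are meant to be overridden when
# better boundaries are available.  `leaflet` records which membrane leaflet a region is
# attributed to for per-leaflet contact reporting: `upper` = outer leaflet (C-terminal
# side), `lower` = inner leaflet (N-terminal side), `both` = spans the bilayer.
regions:
  TM I:      {start: 5,   end: 25,  leaflet: both}
  TM II:     {start: 47,  end: 67,  leaflet: both}
  TM III:    {start: 79,  end: 101, leaflet: both}
  TM IV:     {start: 110, end: 133, leaflet: both}
  TM V:      {start: 134, end: 157, leaflet: both}
  LP I:      {start: 26,  end: 46,  leaflet: upper}
  LP II:     {start: 68,  end: 78,  leaflet: lower}
  LP III:    {start: 102, end: 109, leaflet: upper}
  LP IV:     {start: 158, end: 169, leaflet: upper}
  CRAC:      {start: 150, end: 156, leaflet: upper}
  CARC:      {start: 135, end: 141, leaflet: lower}
  CRAC-like: {start: 17,  end: 24,  leaflet: upper}
  LAF:       {start: 144, end: 146, leaflet: upper}
  GXXXG:     {start: 83,  end: 87,  leaflet: lower}
  WXPXF:     {start: 95,  end: 99,  leaflet: upper}
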