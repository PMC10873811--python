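Acer
Alabama
Apr
April
Arkansas
Aster
Aug
August
Carex
Carolina
Clay
Collected
Collector
Correll
County
Curtiss
Dec
December
Disturbed
Dry
Duncan
Edge
Eupatorium
Feb
February
Flora
Florida
Georgia
Granite
Greene
Herbarium
Jackson
Jan
January
Jones
Jul
July
Jun
Juncus
June
Kentucky
Kral
Lawrence
Leon
Louisiana
Low
Madison
Mar
March
Marion
May
Mohr
Moist
Monroe
No
Nov
November
Oct
October
Old
Open
Panicum
Pinus
Plants
Quercus
Rocky
Rubus
Salix
Sep
September
Shinners
Small
Solidago
State
Stream
Tennessee
Texas
Travis
University
Viola
Virginia
Walker
alba
and
at
bank
botanical
botany
by
canadensis
creek
det
ditch
elev
fencerow
field
forest
garden
glabra
hardwood
herb
hirsuta
in
label
laevis
leg
limestone
margin
meadow
mixed
museum
national
near
occidentalis
of
on
outcrop
park
pasture
pineland
ravine
rigida
river
road
roadside
sandy
slope
sp
specimen
subsp
tenuifolia
the
var
virginiana
vulgaris
wet
with
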