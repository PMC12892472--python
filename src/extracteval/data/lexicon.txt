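# Built-in coastal-wetland restoration lexicon for the synthetic corpus
# generator.  Format: category<TAB>term.  Categories map to attribute
# roles: site (place names), species (Latin binomials), ecosystem,
# action, method, response.
site	Chesapeake Bay
site	Delaware Bay
site	Hudson River Estuary
site	Tampa Bay
site	Galveston Bay
site	San Francisco Bay
site	Puget Sound
site	Moreton Bay
site	Port Phillip Bay
site	Wadden Sea
site	Venice Lagoon
site	Ebro Delta
site	Rhone Delta
site	Danube Delta
site	Mekong Delta
site	Yellow River Delta
site	Yangtze Estuary
site	Bohai Bay
site	Seto Inland Sea
site	Firth of Forth
site	Morecambe Bay
site	Severn Estuary
site	Humber Estuary
site	Bay of Fundy
site	Laguna Madre
site	Pamlico Sound
site	Albemarle Sound
site	Barnegat Bay
site	Jamaica Bay
site	Narragansett Bay
site	Cape Cod
site	Plum Island
site	Tijuana Estuary
site	Elkhorn Slough
site	Willapa Bay
site	Coos Bay
site	Grays Harbor
site	Oosterschelde
site	Westerschelde
site	Arcachon Bay
site	Ria Formosa
site	Mar Menor
site	Curonian Lagoon
site	Saloum Delta
site	Niger Delta
site	Zambezi Delta
site	Richards Bay
site	Knysna Estuary
site	Spencer Gulf
site	Hauraki Gulf
site	Manukau Harbour
site	Tokyo Bay
site	Ariake Sea
site	Jiaozhou Bay
site	Pearl River Estuary
site	Red River Delta
site	Chilika Lagoon
site	Sundarbans
site	Indus Delta
site	Nile Delta
species	Spartina alterniflora
species	Spartina patens
species	Phragmites australis
species	Zostera marina
species	Zostera noltii
species	Posidonia oceanica
species	Thalassia testudinum
species	Halodule wrightii
species	Ruppia maritima
species	Salicornia europaea
species	Sarcocornia perennis
species	Juncus roemerianus
species	Distichlis spicata
species	Avicennia marina
species	Avicennia germinans
species	Rhizophora mangle
species	Rhizophora apiculata
species	Laguncularia racemosa
species	Sonneratia alba
species	Kandelia obovata
species	Crassostrea virginica
species	Crassostrea gigas
species	Ostrea edulis
species	Mytilus edulis
species	Mercenaria mercenaria
species	Mya arenaria
species	Macoma balthica
species	Cerastoderma edule
species	Callinectes sapidus
species	Carcinus maenas
species	Uca pugnax
species	Littorina littorea
species	Fundulus heteroclitus
species	Cyprinodon variegatus
species	Anguilla anguilla
species	Salmo salar
species	Oncorhynchus keta
species	Morone saxatilis
species	Sciaenops ocellatus
species	Mugil cephalus
species	Palaemonetes pugio
species	Penaeus monodon
species	Nereis diversicolor
species	Arenicola marina
species	Corophium volutator
species	Hydrobia ulvae
species	Tringa totanus
species	Calidris alpina
species	Egretta garzetta
species	Ardea alba
species	Platalea leucorodia
species	Branta bernicla
ecosystem	salt marsh
ecosystem	seagrass meadow
ecosystem	mangrove forest
ecosystem	tidal flat
ecosystem	mudflat
ecosystem	oyster reef
ecosystem	coastal lagoon
ecosystem	estuary
ecosystem	brackish marsh
ecosystem	freshwater wetland
ecosystem	tidal creek
ecosystem	sand dune
ecosystem	shellfish bed
ecosystem	kelp forest
ecosystem	intertidal zone
ecosystem	barrier island
ecosystem	deltaic plain
ecosystem	reed bed
ecosystem	sedge meadow
ecosystem	eelgrass bed
action	managed realignment
action	tidal reinstatement
action	hydrological restoration
action	sediment addition
action	thin layer placement
action	dike removal
action	culvert replacement
action	channel excavation
action	invasive species removal
action	revegetation
action	replanting
action	seeding
action	transplanting
action	living shoreline construction
action	breakwater installation
action	oyster reef construction
action	grazing exclusion
action	nutrient reduction
action	freshwater diversion
action	marsh terracing
action	shoreline stabilization
action	habitat creation
action	propagule planting
action	weir installation
action	embankment breaching
action	drainage blocking
action	mangrove planting
action	dune fencing
method	vegetation survey
method	quadrat sampling
method	transect survey
method	benthic core sampling
method	sediment coring
method	water quality monitoring
method	salinity measurement
method	elevation survey
method	drone imagery
method	satellite remote sensing
method	aerial photography
method	fish trapping
method	seine netting
method	fyke netting
method	point count survey
method	invertebrate sampling
method	soil sampling
method	porewater sampling
method	turbidity measurement
method	nutrient analysis
method	stable isotope analysis
method	biomass harvesting
method	litterfall collection
method	accretion measurement
method	surface elevation table
method	camera trapping
method	acoustic monitoring
method	tide gauge
method	piezometer monitoring
response	species richness
response	vegetation cover
response	stem density
response	aboveground biomass
response	belowground biomass
response	shoot density
response	survival rate
response	recruitment
response	sediment accretion
response	soil organic carbon
response	carbon sequestration
response	nitrogen concentration
response	phosphorus concentration
response	water depth
response	inundation frequency
response	fish abundance
response	bird abundance
response	invertebrate density
response	macrofauna diversity
response	canopy height
response	seed production
response	germination rate
response	porewater sulfide
response	redox potential
response	chlorophyll concentration
response	primary productivity
response	shellfish biomass
response	nekton density
response	community composition
response	erosion rate
response	elevation change
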