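<?xml version='1.0' encoding='utf-8'?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xsi:schemaLocation="http://graphml.graphdrawing.org/xmlns http://graphml.graphdrawing.org/xmlns/1.0/graphml.xsd"><key id="d0" for="edge" attr.name="score" attr.type="long"/>
<graph edgedefault="undirected"><node id="CDC42"/>
<node id="CTNNB1"/>
<node id="ERBB2"/>
<node id="MAPK3"/>
<node id="MYC"/>
<node id="PIK3CA"/>
<node id="RHOA"/>
<edge source="CDC42" target="CTNNB1">
  <data key="d0">960</data>
</edge>
<edge source="CDC42" target="ERBB2">
  <data key="d0">950</data>
</edge>
<edge source="CDC42" target="MAPK3">
  <data key="d0">980</data>
</edge>
<edge source="CDC42" target="PIK3CA">
  <data key="d0">910</data>
</edge>
<edge source="CTNNB1" target="ERBB2">
  <data key="d0">905</data>
</edge>
<edge source="CTNNB1" target="RHOA">
  <data key="d0">970</data>
</edge>
<edge source="ERBB2" target="MYC">
  <data key="d0">999</data>
</edge>
<edge source="MAPK3" target="MYC">
  <data key="d0">930</data>
</edge>
</graph></graphml>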