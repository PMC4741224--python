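<?xml version="1.0" encoding="UTF-8"?>
<!-- Conservative subset of the Taxon Concept Transfer Schema (TCS) used
     for the botanical/fungal registration channel: a batch of TaxonName
     records with rank, nomenclatural status, basionym pointer and the
     publication citation. The response dialect is identical plus one
     RegistryIdentifier element per record. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.tdwg.org/schemas/tcs/1.01"
           xmlns:tcs="http://www.tdwg.org/schemas/tcs/1.01"
           elementFormDefault="qualified">

  <xs:element name="DataSet">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="MetaData" type="tcs:MetaDataType" minOccurs="0"/>
        <xs:element name="TaxonNames">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="TaxonName" type="tcs:TaxonNameType"
                          minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="MetaDataType">
    <xs:sequence>
      <xs:element name="PublicationCitation">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="Title" type="xs:string"/>
            <xs:element name="Journal" type="xs:string" minOccurs="0"/>
            <xs:element name="ISSN" type="xs:string" minOccurs="0"/>
            <xs:element name="DOI" type="xs:string" minOccurs="0"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="TaxonNameType">
    <xs:sequence>
      <xs:element name="Simple" type="xs:string"/>
      <xs:element name="Rank" type="xs:string" minOccurs="0"/>
      <xs:element name="CanonicalName" type="xs:string" minOccurs="0"/>
      <xs:element name="CanonicalAuthorship" type="xs:string" minOccurs="0"/>
      <xs:element name="NomenclaturalStatus" type="xs:string"/>
      <xs:element name="Basionym" type="xs:string" minOccurs="0"/>
      <xs:element name="TypificationKind" minOccurs="0">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="holotype"/>
            <xs:enumeration value="lectotype"/>
            <xs:enumeration value="neotype"/>
            <xs:enumeration value="epitype"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:element>
      <xs:element name="RegistryIdentifier" type="xs:string" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="nomenclaturalCode" use="required">
      <xs:simpleType>
        <xs:restriction base="xs:string">
          <xs:enumeration value="Botanical"/>
          <xs:enumeration value="Zoological"/>
        </xs:restriction>
      </xs:simpleType>
    </xs:attribute>
    <xs:attribute name="isHybrid" type="xs:boolean"/>
  </xs:complexType>

</xs:schema>
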